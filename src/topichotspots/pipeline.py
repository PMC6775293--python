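"""Per-year orchestration: LDA topics -> AP clusters -> central-topic summaries.

For each year's corpus the pipeline fits the topic model, clusters the K
topic-word rows by affinity propagation, and summarizes every cluster by its
exemplar topic's top-weighted words (the "central topic" / research hotspot
for that year). Trends are computed downstream on words and categories, not
by aligning topics across years.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ap import APConfig, APResult, affinity_propagation, build_similarity
from .corpus import Corpus
from .lda import GibbsLDA, LDAConfig, fit_lda, top_words


@dataclass
class ClusterSummary:
    """One AP cluster summarized by its exemplar topic's ranked words."""

    year: int | str
    exemplar_topic: int
    member_topics: list[int]
    words: list[tuple[str, float]]

    @property
    def size(self) -> int:
        return len(self.member_topics)

    @property
    def top_word(self) -> str:
        return self.words[0][0]


@dataclass
class YearResult:
    year: int | str
    model: GibbsLDA
    ap: APResult
    summaries: list[ClusterSummary]
    config: dict


def run_year(
    corpus: Corpus,
    lda_config: LDAConfig | None = None,
    ap_config: APConfig | None = None,
    n_words: int = 20,
    similarity: str = "neg-reciprocal",
) -> YearResult:
    """Fit LDA on one year's corpus, cluster its topics, summarize clusters."""
    lda_config = lda_config or LDAConfig()
    ap_config = ap_config or APConfig()
    model = fit_lda(corpus, lda_config)
    K = lda_config.n_topics

    if K < 2:
        warnings.warn("fewer than 2 topics; AP skipped", stacklevel=2)
        ap_result = APResult([0], np.zeros(K, dtype=np.int64), 0, True)
    else:
        sim = build_similarity(
            model.phi_, ap_config.preference_strategy, similarity
        )
        ap_result = affinity_propagation(sim, ap_config)

    summaries = []
    clusters = ap_result.clusters()
    for exemplar in ap_result.exemplars:
        summaries.append(
            ClusterSummary(
                year=corpus.year,
                exemplar_topic=exemplar,
                member_topics=sorted(clusters[exemplar]),
                words=top_words(model.phi_, corpus.vocabulary, exemplar, n_words),
            )
        )
    config = {
        "lda": {
            "n_topics": lda_config.n_topics,
            "alpha": lda_config.alpha,
            "beta": lda_config.beta,
            "n_iterations": lda_config.n_iterations,
            "seed": lda_config.seed,
        },
        "ap": {
            "damping": ap_config.damping,
            "max_iter": ap_config.max_iter,
            "convergence_window": ap_config.convergence_window,
            "preference_strategy": ap_config.preference_strategy,
            "similarity": similarity,
        },
        "n_words": n_words,
    }
    return YearResult(
        year=corpus.year, model=model, ap=ap_result, summaries=summaries,
        config=config,
    )


def year_seed(master_seed: int, year: int) -> int:
    """Deterministic per-year sampler seed derived from one master seed."""
    return (master_seed * 1_000_003 + year * 7919) % (2**31)


def run_pipeline(
    corpora: dict[int, Corpus],
    lda_config: LDAConfig | None = None,
    ap_config: APConfig | None = None,
    n_words: int = 20,
    master_seed: int = 0,
    similarity: str = "neg-reciprocal",
) -> list[YearResult]:
    """Run the per-year stage over a year->corpus map with derived seeds."""
    base = lda_config or LDAConfig()
    results = []
    for year in sorted(corpora):
        cfg = LDAConfig(
            n_topics=base.n_topics,
            alpha=base.alpha,
            beta=base.beta,
            n_iterations=base.n_iterations,
            seed=year_seed(master_seed, year),
        )
        results.append(
            run_year(corpora[year], cfg, ap_config, n_words, similarity)
        )
    return results


def _summary_order(summaries: list[ClusterSummary]) -> list[ClusterSummary]:
    """Descending cluster size, ties by exemplar topic index."""
    return sorted(summaries, key=lambda s: (-s.size, s.exemplar_topic))


def central_words(results: list[YearResult]) -> dict[int | str, list[str]]:
    """Per year, each cluster's highest-weight word (the topic center),
    largest clusters first."""
    if not results:
        raise ValueError("no results")
    return {
        res.year: [s.top_word for s in _summary_order(res.summaries)]
        for res in results
    }


def merge_year_words(result: YearResult) -> list[tuple[str, float]]:
    """Union of one year's summary words; a word's weight is the sum of its
    weights across summaries. Sorted descending, ties lexicographic.
    This is the word-cloud input table."""
    merged: dict[str, float] = {}
    for summary in result.summaries:
        for term, weight in summary.words:
            merged[term] = merged.get(term, 0.0) + weight
    return sorted(merged.items(), key=lambda tw: (-tw[1], tw[0]))


def write_year_result(result: YearResult, out_dir: str | Path) -> None:
    """Serialize one year: sidecar JSON, AP JSON, summaries TSV, merged TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(result.config, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out / "ap.json").write_text(
        json.dumps(
            {
                "exemplars": result.ap.exemplars,
                "labels": [int(x) for x in result.ap.labels],
                "iterations_run": result.ap.iterations_run,
                "converged": result.ap.converged,
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    with open(out / "summaries.tsv", "w", encoding="utf-8") as fh:
        fh.write("year\tcluster\trank\tterm\tweight\n")
        for c, summary in enumerate(_summary_order(result.summaries)):
            for rank, (term, weight) in enumerate(summary.words, start=1):
                fh.write(
                    f"{result.year}\t{c}\t{rank}\t{term}\t{weight:.10e}\n"
                )
    with open(out / "merged_words.tsv", "w", encoding="utf-8") as fh:
        fh.write("term\tweight\n")
        for term, weight in merge_year_words(result):
            fh.write(f"{term}\t{weight:.10e}\n")


def load_summaries_tsv(path: str | Path) -> list[ClusterSummary]:
    """Read a summaries TSV back into ClusterSummary objects (word lists
    only; member lists are not stored in the TSV)."""
    rows: dict[int, list[tuple[str, float]]] = {}
    year: int | str = "pooled"
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            y, c, _rank, term, weight = line.rstrip("\n").split("\t")
            year = int(y) if y.isdigit() else y
            rows.setdefault(int(c), []).append((term, float(weight)))
    return [
        ClusterSummary(year=year, exemplar_topic=c, member_topics=[c],
                       words=words)
        for c, words in sorted(rows.items())
    ]
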