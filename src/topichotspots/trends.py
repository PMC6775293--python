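"""Cross-year analytics over central-topic summaries.

Turns the per-year hotspot summaries into the framework's trend products:
term categorization against a MeSH-style term->category table, per-category
occurrence tables (which years a disease/chemical/symptom term was a hotspot
in, and in how many of a year's clusters), per-year category proportions,
gene-symbol extraction from hotspot words, and a local hypergeometric
gene-set enrichment with Benjamini-Hochberg FDR over GMT collections.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .pipeline import ClusterSummary, YearResult


@dataclass
class TermCategoryMap:
    """Lowercase term -> category label; first mapping wins on duplicates."""

    mapping: dict[str, str]
    source_hash: str = ""

    @property
    def categories(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def terms_in(self, category: str) -> list[str]:
        return sorted(t for t, c in self.mapping.items() if c == category)


def load_term_categories(path: str | Path) -> TermCategoryMap:
    """Read a term<TAB>category file; lines starting with '#' are comments."""
    raw = Path(path).read_bytes()
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(raw.decode("utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected term<TAB>category")
        term, category = parts[0].strip().lower(), parts[1].strip()
        if term in mapping:
            warnings.warn(
                f"duplicate mapping for {term!r}; keeping {mapping[term]!r}",
                stacklevel=2,
            )
            continue
        mapping[term] = category
    return TermCategoryMap(mapping, hashlib.sha256(raw).hexdigest()[:16])


@dataclass
class EnrichmentResult:
    name: str
    overlap: int
    set_size: int
    p_value: float
    fdr: float
    overlap_genes: list[str] = field(default_factory=list)


def unique_central_words(results: list[YearResult]) -> set[str]:
    """Deduplicated union of all summary words across all years."""
    words: set[str] = set()
    for res in results:
        for summary in res.summaries:
            words.update(term for term, _ in summary.words)
    return words


def categorize(
    terms: set[str], category_map: TermCategoryMap
) -> tuple[dict[str, str], float]:
    """Label each term with its category ('uncategorized' if unmapped);
    returns (labels, coverage fraction)."""
    labels = {
        t: category_map.mapping.get(t.lower(), "uncategorized") for t in terms
    }
    if terms:
        covered = sum(1 for c in labels.values() if c != "uncategorized")
        coverage = covered / len(terms)
    else:
        coverage = 0.0
    return labels, coverage


def _iter_summaries(results) -> list[ClusterSummary]:
    out = []
    for res in results:
        out.extend(res.summaries if isinstance(res, YearResult) else [res])
    return out


def occurrence_table(
    results: list[YearResult],
    category_map: TermCategoryMap,
    category: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Presence table for one category: years x the category's terms, cell =
    number of that year's cluster summaries containing the term. Also returns
    the per-term number of years present (the hotspot "frequency")."""
    terms = category_map.terms_in(category)
    if not terms and category not in category_map.categories:
        raise ValueError(
            f"unknown category {category!r}; known: {category_map.categories}"
        )
    years = sorted({res.year for res in results})
    table = pd.DataFrame(0, index=years, columns=terms, dtype=int)
    for res in results:
        for summary in res.summaries:
            present = {t for t, _ in summary.words}
            for term in terms:
                if term in present:
                    table.loc[res.year, term] += 1
    years_present = (table > 0).sum(axis=0)
    years_present.name = "years_present"
    return table, years_present


def category_proportions(
    results: list[YearResult], category_map: TermCategoryMap
) -> pd.DataFrame:
    """Per-year share of each category among categorized hotspot-word
    occurrences (each appearance of a word in a summary counts once).
    Rows sum to 1 where any categorized occurrence exists; an all-zero row
    means nothing that year was categorized."""
    years = sorted({res.year for res in results})
    categories = category_map.categories
    counts = pd.DataFrame(0.0, index=years, columns=categories)
    for res in results:
        for summary in res.summaries:
            for term, _ in summary.words:
                cat = category_map.mapping.get(term.lower())
                if cat is not None:
                    counts.loc[res.year, cat] += 1
    totals = counts.sum(axis=1)
    zero_years = [y for y, t in totals.items() if t == 0]
    if zero_years:
        warnings.warn(
            f"no categorized words in year(s) {zero_years}", stacklevel=2
        )
    props = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return props


def extract_genes(
    results: list[YearResult],
    gene_lexicon: set[str],
    n_top: int | None = None,
) -> list[str]:
    """Case-insensitive intersection of hotspot words with a gene-symbol
    lexicon; deduplicated, uppercase, sorted.

    Words come from the cluster summaries (the phi-ranked top-N words of each
    exemplar topic). Passing ``n_top`` re-ranks deeper into each exemplar's
    phi row using the fitted models attached to the results."""
    if not gene_lexicon:
        raise ValueError("empty gene lexicon")
    lexicon = {g.upper() for g in gene_lexicon}
    words: set[str] = set()
    if n_top is None:
        words = unique_central_words(results)
    else:
        for res in results:
            for summary in res.summaries:
                words.update(
                    term
                    for term, _ in res.model.top_words(
                        summary.exemplar_topic, n_top
                    )
                )
    return sorted({w.upper() for w in words} & lexicon)


def load_gene_lexicon(path: str | Path) -> set[str]:
    return {
        line.strip().upper()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name<TAB>description<TAB>member genes."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        name, _desc, *genes = parts
        sets[name] = sorted({g.strip().upper() for g in genes if g.strip()})
    return sets


def enrich(
    genes: list[str],
    gene_sets: dict[str, list[str]],
    background_size: int,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of the query genes in each set.

    For a background population of ``background_size`` genes, a set of size
    n, and a query of size N drawn from the background, the p-value is the
    upper tail P(X >= overlap) of Hypergeometric(background_size, n, N).
    FDR is Benjamini-Hochberg across the sets; results sorted by p, ties by
    name."""
    query = {g.upper() for g in genes}
    if background_size < len(query):
        raise ValueError("background smaller than the query gene list")
    names, pvals, rows = [], [], []
    for name in sorted(gene_sets):
        members = {g.upper() for g in gene_sets[name]}
        if len(members) > background_size:
            raise ValueError(
                f"gene set {name!r} larger than the background population"
            )
        overlap_genes = sorted(query & members)
        overlap = len(overlap_genes)
        p = float(
            hypergeom.sf(overlap - 1, background_size, len(members), len(query))
        )
        names.append(name)
        pvals.append(min(p, 1.0))
        rows.append((name, overlap, len(members), overlap_genes))
    if not names:
        return []
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(name, overlap, size, p, float(fdr), overlap_genes)
        for (name, overlap, size, overlap_genes), p, fdr in zip(
            rows, pvals, fdrs
        )
    ]
    return sorted(results, key=lambda r: (r.p_value, r.name))


def write_enrichment_tsv(
    results: list[EnrichmentResult], path: str | Path, header_note: str = ""
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write("set\toverlap\tsize\tp_value\tfdr\toverlap_genes\n")
        for r in results:
            fh.write(
                f"{r.name}\t{r.overlap}\t{r.set_size}\t{r.p_value:.6e}\t"
                f"{r.fdr:.6e}\t{','.join(r.overlap_genes)}\n"
            )
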