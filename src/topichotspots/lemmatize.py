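"""Light rule-based English lemmatizer for abstract text.

Maps inflected surface forms to dictionary lemmas: an irregular-form table,
noun plural suffix rules, and conservative participle (-ing / -ed) stripping
with Porter-style stem restoration. It is intentionally small and fully
deterministic; the token streams it produces are what the topic model sees,
so all downstream results are reproducible from this file alone.

The rules favour precision over recall: a form the rules cannot safely reduce
is returned unchanged rather than over-stemmed ("aging" stays "aging",
"cascades" becomes "cascade", "studies" becomes "study").
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")

# Irregular plurals / forms common in biomedical prose.
_IRREGULAR: dict[str, str] = {
    "mice": "mouse",
    "men": "man",
    "women": "woman",
    "children": "child",
    "teeth": "tooth",
    "feet": "foot",
    "people": "person",
    "analyses": "analysis",
    "hypotheses": "hypothesis",
    "diagnoses": "diagnosis",
    "prognoses": "prognosis",
    "syntheses": "synthesis",
    "apoptoses": "apoptosis",
    "criteria": "criterion",
    "phenomena": "phenomenon",
    "bacteria": "bacterium",
    "mitochondria": "mitochondrion",
    "nuclei": "nucleus",
    "stimuli": "stimulus",
    "fungi": "fungus",
    "foci": "focus",
    "loci": "locus",
    "indices": "index",
    "matrices": "matrix",
    "vertices": "vertex",
    "cortices": "cortex",
    "genera": "genus",
    "species": "species",
    "series": "series",
    "data": "data",
    "media": "media",
    "made": "make",
    "shown": "show",
    "taken": "take",
    "given": "give",
    "found": "find",
    "led": "lead",
    "worse": "bad",
    "better": "good",
}


def _measure(stem: str) -> int:
    """Porter measure: number of vowel→consonant alternations in the stem."""
    m = 0
    prev_vowel = False
    for ch in stem:
        is_vowel = ch in _VOWELS or (ch == "y" and not prev_vowel)
        if prev_vowel and not is_vowel:
            m += 1
        prev_vowel = is_vowel
    return m


def _ends_cvc(stem: str) -> bool:
    if len(stem) < 3:
        return False
    c1, v, c2 = stem[-3], stem[-2], stem[-1]
    return (
        c1 not in _VOWELS
        and v in _VOWELS
        and c2 not in _VOWELS
        and c2 not in "wxy"
    )


def _restore(stem: str) -> str:
    """Undo spelling changes after stripping -ing/-ed (hopp→hop, mak→make)."""
    if stem.endswith(("at", "bl", "iz", "as", "us")):
        return stem + "e"
    if (
        len(stem) >= 2
        and stem[-1] == stem[-2]
        and stem[-1] not in _VOWELS
        and stem[-1] not in "lsz"
    ):
        return stem[:-1]
    if _measure(stem) == 1 and _ends_cvc(stem):
        return stem + "e"
    return stem


def _strip_plural(word: str) -> str:
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("es") and word[:-2].endswith(("ss", "x", "z", "ch", "sh", "us")):
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")) and len(word) > 3:
        return word[:-1]
    return word


def _strip_participle(word: str) -> str:
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"
    for suffix in ("ing", "ed"):
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if len(stem) >= 3 and any(ch in _VOWELS for ch in stem):
                return _restore(stem)
    return word


def lemmatize(word: str) -> str:
    """Return the lemma of a single lowercase alphabetic token."""
    if word in _IRREGULAR:
        return _IRREGULAR[word]
    reduced = _strip_plural(word)
    if reduced != word:
        return _IRREGULAR.get(reduced, reduced)
    return _strip_participle(word)
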