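"""Porter (1980) suffix-stripping stemmer.

Classic rule set, steps 1a-5b, as published in the original algorithm
description. Words of length <= 2 are returned unchanged. The keyword
matcher compares truncated keyword stems against the output of this
function by prefix, so the implementation must agree with the published
algorithm exactly; the unit tests pin it against the example pairs
printed alongside the original rule tables.
"""

from __future__ import annotations

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel-consonant sequences: [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_cons(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant, final consonant not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


# (suffix, replacement) rule tables; within a step the longest matching
# suffix is the only rule attempted.
_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
    ("anci", "ance"), ("izer", "ize"), ("abli", "able"), ("alli", "al"),
    ("entli", "ent"), ("eli", "e"), ("ousli", "ous"), ("ization", "ize"),
    ("ation", "ate"), ("ator", "ate"), ("alism", "al"), ("iveness", "ive"),
    ("fulness", "ful"), ("ousness", "ous"), ("aliti", "al"),
    ("iviti", "ive"), ("biliti", "ble"),
]
_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]
_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]

_STEP2 = sorted(_STEP2, key=lambda r: -len(r[0]))
_STEP3 = sorted(_STEP3, key=lambda r: -len(r[0]))
_STEP4 = sorted(_STEP4, key=len, reverse=True)


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            return w[:-1]
        return w
    stripped = None
    if w.endswith("ed") and _has_vowel(w[:-2]):
        stripped = w[:-2]
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        stripped = w[:-3]
    if stripped is None:
        return w
    w = stripped
    if w.endswith(("at", "bl", "iz")):
        return w + "e"
    if _ends_double_cons(w) and w[-1] not in "lsz":
        return w[:-1]
    if _measure(w) == 1 and _ends_cvc(w):
        return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _has_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


def _rule_table(w: str, rules, min_measure: int) -> str:
    for suffix, repl in rules:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > min_measure - 1:
                return stem + repl
            return w
    return w


def _step4(w: str) -> str:
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion" and not stem.endswith(("s", "t")):
                    return w
                return stem
            return w
    return w


def _step5(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]
    return w


def has_strippable_suffix(entry: str) -> bool:
    """True when the suffix-stripping steps (1b-4) would rewrite ``entry``.

    Used to validate keyword stem entries: a truncated stem such as
    "hydrolys" passes (only the letter-level normalizations 1a, 1c and 5
    touch it), while an inflected form such as "formed" carries a
    removable suffix and fails.
    """
    w = _step1a(entry.lower())
    if _step1b(w) != w:
        return True
    w = _step1c(w)
    v = _rule_table(w, _STEP2, 1)
    v = _rule_table(v, _STEP3, 1)
    v = _step4(v)
    return v != w


def porter_stem(word: str) -> str:
    """Return the Porter stem of ``word`` (lowercased first)."""
    w = word.lower()
    if len(w) <= 2:
        return w
    w = _step1a(w)
    w = _step1b(w)
    w = _step1c(w)
    w = _rule_table(w, _STEP2, 1)
    w = _rule_table(w, _STEP3, 1)
    w = _step4(w)
    w = _step5(w)
    return w
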