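"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the production code paths (no regex, no
precompiled patterns, no short-circuiting): terms are matched by scanning
every start position of every token and checking word boundaries
character by character.
"""

from __future__ import annotations


def naive_term_in_token(
    term: str, token: str, case_fold: bool = True, word_boundary: bool = True
) -> bool:
    if case_fold:
        term = term.casefold()
        token = token.casefold()
    n, m = len(token), len(term)
    for i in range(n - m + 1):
        if token[i : i + m] != term:
            continue
        if word_boundary:
            def is_word(c):
                return c.isalnum() or c == "_"

            if i > 0 and is_word(token[i - 1]):
                continue
            if i + m < n and is_word(token[i + m]):
                continue
        return True
    return False


def naive_classify(tokens: list[str], lexicon) -> str:
    """Decision rules re-applied by exhaustive scanning, no indexing."""
    if not tokens:
        return "UNCLASSIFIABLE"
    cf = lexicon.matching_policy.case_fold
    wb = lexicon.matching_policy.word_boundary

    upf_found = False
    for token in tokens:
        for marker in lexicon.upf_markers:
            if naive_term_in_token(marker.term, token, cf, wb):
                upf_found = True
    if upf_found:
        return "NOVA4"

    def is_culinary(token):
        found = False
        for term in lexicon.culinary_terms:
            if naive_term_in_token(term, token, cf, wb):
                found = True
        return found

    non_water = [t for t in tokens if t.strip() != "water"]
    if non_water and all(is_culinary(t) for t in non_water):
        return "NOVA2"

    any_culinary = any(is_culinary(t) for t in tokens)
    any_plain = any(
        not is_culinary(t) and t.strip() != "water" for t in tokens
    )
    if any_culinary and any_plain:
        return "NOVA3"
    return "NOVA1"
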