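"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately re-derive results with naive literal logic (string
enumeration, all-pairs counting) so the production implementations are
checked against something that shares no code with them.
"""
import itertools


def naive_match(pattern: str, code: str) -> bool:
    """Literal-semantics evaluation of one diagnosis-code pattern."""
    p = pattern.upper().replace("–", "-")
    c = code.upper()
    if p.endswith("X") and len(p) > 3:
        stem = p[:-1]
        base = stem[:-1] if stem.endswith(".") else stem
        return c == base or c.startswith(stem) or c.startswith(base + ".")
    if "-" in p:
        lo, hi = p.split("-")
        return c[:3].isdigit() and int(lo) <= int(c[:3]) <= int(hi)
    if len(p) == 3:
        return c[:3] == p and (len(c) == 3 or c[3] == ".")
    return c == p


def naive_list_match(code_list, code: str) -> bool:
    return (any(naive_match(p, code) for p in code_list.include_patterns)
            and not any(naive_match(p, code)
                        for p in code_list.exclude_patterns))


def candidate_universe(step: int = 7) -> list[str]:
    """A dense universe of candidate ICD-9 / ICD-10 code strings: a sweep
    of numeric roots, every root named in the shipped lists (and its
    neighbours), F-codes, and a spread of one- and two-digit suffixes."""
    roots = [f"{r:03d}" for r in range(0, 1000, step)]
    roots += ["139", "140", "173", "209", "210", "224", "226", "229", "232",
              "233", "239", "240", "250", "327", "331", "345", "357", "362",
              "366", "398", "401", "402", "403", "404", "405", "412", "413",
              "415", "425", "427", "428", "438", "440", "441", "442", "443",
              "453", "491", "492", "494", "495", "496", "500", "505", "506",
              "555", "556", "714", "733"]
    roots += [f"F{r:02d}" for r in range(0, 100, 3)]
    roots += ["F10", "F20", "F25", "F31", "F32", "F33", "F41", "F43", "F90"]
    suffixes = ["", ".0", ".1", ".2", ".3", ".9", ".01", ".03", ".11", ".13",
                ".21", ".23", ".31", ".35", ".41", ".89", ".91", ".93"]
    return sorted({r + s for r in roots for s in suffixes})


def all_pairs_concordance(predicted, outcome) -> float:
    """O(n^2) c-statistic: compare every event/non-event pair, ties 0.5."""
    events = [p for p, y in zip(predicted, outcome) if y]
    nonevents = [p for p, y in zip(predicted, outcome) if not y]
    num = sum(1.0 if pe > pn else 0.5 if pe == pn else 0.0
              for pe, pn in itertools.product(events, nonevents))
    return num / (len(events) * len(nonevents))
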