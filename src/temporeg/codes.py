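"""Diagnosis-code phenotyping: a small pattern grammar over ICD-9-CM and
ICD-10 code strings, and named condition code lists with include / exclude
("BUT NOT") semantics.

Supported pattern forms
-----------------------
literal      ``714.0`` / ``F43.1``  — exact, case-insensitive match
prefix       ``427.3x`` / ``F10.x`` — the trailing ``x`` matches any suffix,
             including the empty one, so ``427.3x`` matches both ``427.3``
             and ``427.31``, and ``491.x`` matches the bare root ``491``
bare root    ``173``               — any code whose 3-character root is 173
root range   ``140-239``           — any code whose root falls in the
             inclusive range; roots are the first three characters
             (ICD-9: three digits; ICD-10: letter plus two digits)

A code matches a :class:`CodeList` iff it matches at least one include
pattern and none of the exclude patterns.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import yaml

from .errors import CodePatternError

Matcher = Callable[[str], bool]

_ICD9_ROOT = re.compile(r"^\d{3}")
_ICD10_ROOT = re.compile(r"^[A-Z]\d{2}")
_LITERAL = re.compile(r"^(?:\d{3}|[A-Z]\d{2})(?:\.?[0-9A-Z]+)?$")


def _normalize(code: str) -> str:
    return code.strip().upper().replace("–", "-")


def _root_key(token: str):
    """Comparable root key, or None if the token has no recognisable root."""
    m = _ICD9_ROOT.match(token)
    if m and (len(token) == 3 or not token[3].isdigit()):
        return (0, int(m.group()))
    m = _ICD10_ROOT.match(token)
    if m and (len(token) == 3 or not token[3].isdigit()):
        return (1, token[0], int(token[1:3]))
    return None


def _code_root(code: str):
    if _ICD9_ROOT.match(code):
        return (0, int(code[:3]))
    if _ICD10_ROOT.match(code):
        return (1, code[0], int(code[1:3]))
    return None


def parse_code_pattern(pattern: str) -> Matcher:
    """Compile one pattern into a predicate on code strings.

    Raises :class:`CodePatternError` naming the pattern if it does not fit
    the grammar.
    """
    pat = _normalize(pattern)
    if not pat:
        raise CodePatternError(f"empty code pattern: {pattern!r}")

    if pat.endswith("X") and _root_key(pat[:3]) is not None and len(pat) > 3:
        stem = pat[:-1]
        base = stem.rstrip(".")
        if not _LITERAL.match(base):
            raise CodePatternError(f"malformed prefix pattern: {pattern!r}")
        dotted = base + "."

        def match_prefix(code: str, *, _stem=stem, _base=base, _dot=dotted) -> bool:
            c = _normalize(code)
            return c == _base or c.startswith(_stem) or c.startswith(_dot)

        return match_prefix

    if "-" in pat:
        lo_s, _, hi_s = pat.partition("-")
        lo, hi = _root_key(lo_s.strip()), _root_key(hi_s.strip())
        if lo is None or hi is None or lo_s.strip() != lo_s.strip()[:3] or hi_s.strip() != hi_s.strip()[:3]:
            raise CodePatternError(f"malformed range pattern: {pattern!r}")
        if lo[0] != hi[0] or lo > hi:
            raise CodePatternError(f"invalid range endpoints: {pattern!r}")

        def match_range(code: str, *, _lo=lo, _hi=hi) -> bool:
            root = _code_root(_normalize(code))
            return root is not None and _lo <= root <= _hi

        return match_range

    if len(pat) == 3 and _root_key(pat) is not None:
        key = _root_key(pat)

        def match_root(code: str, *, _key=key) -> bool:
            return _code_root(_normalize(code)) == _key

        return match_root

    if _LITERAL.match(pat):
        def match_literal(code: str, *, _pat=pat) -> bool:
            return _normalize(code) == _pat

        return match_literal

    raise CodePatternError(f"malformed code pattern: {pattern!r}")


@dataclass(frozen=True)
class CodeList:
    """A named condition defined by include patterns minus exclude patterns."""

    condition_name: str
    code_system: str
    include_patterns: tuple[str, ...]
    exclude_patterns: tuple[str, ...] = ()
    _include: tuple[Matcher, ...] = field(init=False, repr=False, compare=False)
    _exclude: tuple[Matcher, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not self.include_patterns:
            raise CodePatternError(
                f"code list {self.condition_name!r} has no include patterns")
        object.__setattr__(self, "_include",
                           tuple(parse_code_pattern(p) for p in self.include_patterns))
        object.__setattr__(self, "_exclude",
                           tuple(parse_code_pattern(p) for p in self.exclude_patterns))

    def matches(self, code: str) -> bool:
        return any(m(code) for m in self._include) and not any(
            m(code) for m in self._exclude)

    def example_codes(self) -> list[str]:
        """Concrete codes guaranteed to match this list.

        Used by the synthetic generator so emitted diagnoses exercise the
        matcher with realistic, suffixed codes.
        """
        cands: set[str] = set()
        for pat in self.include_patterns:
            p = _normalize(pat)
            if p.endswith("X") and len(p) > 3:
                stem, base = p[:-1], p[:-1].rstrip(".")
                sep = "" if stem.endswith(".") or "." in base else "."
                cands.add(base)
                for d in "019":
                    cands.add(stem + d if stem != base else base + sep + d)
            elif "-" in p:
                lo, hi = p.split("-")
                klo, khi = _root_key(lo), _root_key(hi)
                if klo[0] == 0:  # numeric roots: enumerate
                    for r in range(klo[1], khi[1] + 1):
                        cands.update({f"{r:03d}", f"{r:03d}.0", f"{r:03d}.9"})
            elif len(p) == 3:
                cands.update({p, p + ".0", p + ".9"})
            else:
                cands.add(p)
        return sorted(c for c in cands if self.matches(c))


def load_code_lists(path=None) -> dict[str, CodeList]:
    """Load condition code lists keyed by condition name.

    Reads the packaged YAML resource by default; pass ``path`` to use a
    custom file in the same format (groups with a ``code_system`` and a
    ``conditions`` mapping of include/exclude pattern lists).
    """
    if path is None:
        text = resources.files("temporeg.data").joinpath(
            "code_lists.yaml").read_text()
    else:
        from pathlib import Path
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    lists: dict[str, CodeList] = {}
    for group in raw.values():
        system = group["code_system"]
        for name, spec in group["conditions"].items():
            lists[name] = CodeList(
                condition_name=name,
                code_system=system,
                include_patterns=tuple(spec["include"]),
                exclude_patterns=tuple(spec.get("exclude", ())),
            )
    return lists
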