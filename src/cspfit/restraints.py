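"""Ambiguous interaction restraints (AIRs) in the CNS ``.tbl`` dialect.

An AIR is an ambiguous distance restraint between an "active" residue of
one molecule and *any* active or passive residue of the partner; sets of
such restraints derived from chemical-shift-perturbation data drive
data-guided docking. This module builds AIR sets from differential-CSP
patches and serialises them in the dialect consumed by CNS-based docking
engines, stopping short of the docking run itself.

Serialisation grammar (one ``assign`` block per active residue; ``!``
starts a comment; whitespace and newlines are free):

    file      := block*
    block     := "assign" sel or-sel NUM NUM NUM
    sel       := "(" "segid" ID "and" "resid" INT ")"
    or-sel    := "(" sel ( "or" sel )* ")"

The three numbers are the target distance, the lower-bound subtraction
and the upper-bound addition (Å), defaulting to 2.0 / 0.0 / 2.0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

__all__ = ["AIRSet", "build_airset", "write_air_tbl", "read_air_tbl"]


@dataclass(frozen=True)
class AIRSet:
    """Active/passive residue selections for two molecules plus distance bounds."""

    segid_A: str
    active_A: tuple[int, ...]
    segid_B: str
    active_B: tuple[int, ...]
    passive_A: tuple[int, ...] = ()
    passive_B: tuple[int, ...] = ()
    distance_bound: float = 2.0
    lower_bound: float = 0.0
    upper_correction: float = 2.0

    def __post_init__(self) -> None:
        # both sides active in a full AIR set; one-sided sets arise from
        # minimal hand-written files and are allowed on read
        if not self.active_A and not self.active_B:
            raise ValueError("at least one active residue required")
        if self.segid_A == self.segid_B:
            raise ValueError("segids must be distinct")
        for seg, act, pas in (
            (self.segid_A, self.active_A, self.passive_A),
            (self.segid_B, self.active_B, self.passive_B),
        ):
            overlap = set(act) & set(pas)
            if overlap:
                raise ValueError(
                    f"segid {seg}: residues {sorted(overlap)} both active and passive"
                )
        object.__setattr__(self, "active_A", tuple(sorted(self.active_A)))
        object.__setattr__(self, "active_B", tuple(sorted(self.active_B)))
        object.__setattr__(self, "passive_A", tuple(sorted(self.passive_A)))
        object.__setattr__(self, "passive_B", tuple(sorted(self.passive_B)))

    @property
    def n_blocks(self) -> int:
        return len(self.active_A) + len(self.active_B)


def build_airset(
    patch_A: Sequence[int],
    patch_B: Sequence[int],
    segid_A: str = "A",
    segid_B: str = "B",
    passive_A: Sequence[int] = (),
    passive_B: Sequence[int] = (),
    distance_bound: float = 2.0,
    lower_bound: float = 0.0,
    upper_correction: float = 2.0,
) -> AIRSet:
    """Assemble an AIRSet from active patches (and optional passive lists).

    Passive residues are caller-supplied; docking engines that derive them
    automatically (from solvent accessibility around the actives) may be
    given empty lists here and do so themselves.
    """
    if not patch_A or not patch_B:
        raise ValueError("active patches must be non-empty")
    return AIRSet(
        segid_A=segid_A, active_A=tuple(patch_A),
        segid_B=segid_B, active_B=tuple(patch_B),
        passive_A=tuple(passive_A), passive_B=tuple(passive_B),
        distance_bound=distance_bound, lower_bound=lower_bound,
        upper_correction=upper_correction,
    )


def _partner_selection(segid: str, residues: Sequence[int]) -> str:
    sels = [f"(segid {segid} and resid {r})" for r in residues]
    return "(" + "\n        or ".join(sels) + ")"


def write_air_tbl(airset: AIRSet, path: str | Path) -> None:
    """One ``assign`` block per active residue, each against the partner's
    active ∪ passive residues; ``read_air_tbl`` inverts this exactly."""
    lines = ["! ambiguous interaction restraints"]
    for seg_from, actives, seg_to, partner_act, partner_pas in (
        (airset.segid_A, airset.active_A, airset.segid_B, airset.active_B, airset.passive_B),
        (airset.segid_B, airset.active_B, airset.segid_A, airset.active_A, airset.passive_A),
    ):
        partner = sorted(set(partner_act) | set(partner_pas))
        for res in actives:
            lines.append(
                f"assign (segid {seg_from} and resid {res})\n"
                f"       {_partner_selection(seg_to, partner)}\n"
                f"       {airset.distance_bound:g} {airset.lower_bound:g} "
                f"{airset.upper_correction:g}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("!", 1)[0]
        for m in _TOKEN_RE.finditer(line):
            tokens.append((m.group(0), lineno))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, int]]):
        self.tokens = tokens
        self.pos = 0

    def _err(self, msg: str):
        lineno = self.tokens[self.pos][1] if self.pos < len(self.tokens) else (
            self.tokens[-1][1] if self.tokens else 0
        )
        raise ValueError(f"line {lineno}: {msg}")

    def peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self, expect: str | None = None) -> str:
        if self.pos >= len(self.tokens):
            lineno = self.tokens[-1][1] if self.tokens else 0
            raise ValueError(f"line {lineno}: unexpected end of file")
        tok, _ = self.tokens[self.pos]
        if expect is not None and tok.lower() != expect:
            self._err(f"expected {expect!r}, got {tok!r}")
        self.pos += 1
        return tok

    def selection(self) -> tuple[str, int]:
        self.take("(")
        self.take("segid")
        segid = self.take()
        self.take("and")
        self.take("resid")
        tok = self.take()
        try:
            resid = int(tok)
        except ValueError:
            self._err(f"bad residue number {tok!r}")
        self.take(")")
        return segid, resid

    def or_selection(self) -> list[tuple[str, int]]:
        self.take("(")
        sels = [self.selection()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.take("or")
            sels.append(self.selection())
        self.take(")")
        return sels

    def number(self) -> float:
        tok = self.take()
        try:
            return float(tok)
        except ValueError:
            self._err(f"expected a number, got {tok!r}")

    def block(self):
        self.take("assign")
        left = self.selection()
        right = self.or_selection()
        dist = (self.number(), self.number(), self.number())
        return left, right, dist


def read_air_tbl(path: str | Path) -> AIRSet:
    """Parse a ``.tbl`` file written by :func:`write_air_tbl` (or by hand).

    Active residues are those appearing on the left of an ``assign``;
    passives are partner-selection residues that are never active.
    Malformed files raise ``ValueError`` with the offending line number.
    """
    text = Path(path).read_text(encoding="utf-8")
    parser = _Parser(_tokenize(text))
    blocks = []
    while parser.peek() is not None:
        blocks.append(parser.block())
    if not blocks:
        raise ValueError(f"{path}: no assign blocks found")
    active: dict[str, set[int]] = {}
    referenced: dict[str, set[int]] = {}
    dist = blocks[0][2]
    seg_order: list[str] = []
    for (seg, res), partner, d in blocks:
        if d != dist:
            raise ValueError(
                f"{path}: inconsistent distance bounds {d} vs {dist}"
            )
        if seg not in seg_order:
            seg_order.append(seg)
        active.setdefault(seg, set()).add(res)
        for pseg, pres in partner:
            referenced.setdefault(pseg, set()).add(pres)
    segids = sorted(set(seg_order) | set(referenced))
    if len(segids) != 2:
        raise ValueError(f"{path}: expected exactly 2 segids, found {segids}")
    seg_a = seg_order[0]
    seg_b = next(s for s in segids if s != seg_a)
    return AIRSet(
        segid_A=seg_a,
        active_A=tuple(sorted(active.get(seg_a, ()))),
        segid_B=seg_b,
        active_B=tuple(sorted(active.get(seg_b, ()))),
        passive_A=tuple(sorted(referenced.get(seg_a, set()) - active.get(seg_a, set()))),
        passive_B=tuple(sorted(referenced.get(seg_b, set()) - active.get(seg_b, set()))),
        distance_bound=dist[0], lower_bound=dist[1], upper_correction=dist[2],
    )
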