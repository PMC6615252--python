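"""Peptide mass bookkeeping for titration ligands.

Computes monoisotopic or average masses of one-letter peptide sequences
(free or N-terminally acetylated), as a sanity check on the synthetic
peptides used as titration ligands. Residue and water masses come from
pyteomics.

Note: commercial synthetic peptides are often N-terminally acetylated,
yet vendor-quoted masses frequently correspond to the unmodified
monoisotopic sum — the default here is therefore ``free`` termini; pass
``n_terminal_modification="acetyl"`` explicitly when the acetylated mass
is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pt_mass

__all__ = ["PeptideSpec", "peptide_mass"]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_MODS = ("free", "acetyl")
_KINDS = ("monoisotopic", "average")
_ACETYL = _pt_mass.Composition(formula="C2H2O")


@dataclass(frozen=True)
class PeptideSpec:
    sequence: str
    n_terminal_modification: str = "free"
    mass_kind: str = "monoisotopic"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in _STANDARD_AA:
                raise ValueError(
                    f"illegal residue {aa!r} at position {i} of {self.sequence!r}"
                )
        if self.n_terminal_modification not in _MODS:
            raise ValueError(f"n_terminal_modification must be one of {_MODS}")
        if self.mass_kind not in _KINDS:
            raise ValueError(f"mass_kind must be one of {_KINDS}")


def peptide_mass(
    spec: PeptideSpec | str,
    n_terminal_modification: str = "free",
    mass_kind: str = "monoisotopic",
) -> float:
    """Mass of a peptide in g/mol (full precision; round only for display).

    Accepts a :class:`PeptideSpec` or a bare sequence plus keyword options.
    The mass is the residue-mass sum plus one water, plus the acetyl mass
    (+42.0106 monoisotopic) for N-terminally acetylated peptides.
    """
    if isinstance(spec, str):
        spec = PeptideSpec(spec, n_terminal_modification, mass_kind)
    average = spec.mass_kind == "average"
    m = _pt_mass.calculate_mass(sequence=spec.sequence, average=average)
    if spec.n_terminal_modification == "acetyl":
        m += _pt_mass.calculate_mass(composition=_ACETYL, average=average)
    return float(m)
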