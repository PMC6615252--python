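import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cspfit import ShiftRecord, ShiftTable

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(label, n=100, displaced=(), displacement_H=0.1, noise=0.0, rng=None):
    """Regular synthetic HSQC table; optionally displace some residues in ¹H
    and add Gaussian noise to both axes."""
    records = []
    for i in range(1, n + 1):
        h = 8.0 + 0.01 * i
        nn = 115.0 + 0.1 * i
        if i in displaced:
            h += displacement_H
        if noise > 0:
            h += rng.normal(0.0, noise)
            nn += rng.normal(0.0, noise)
        records.append(ShiftRecord(i, "A", h, nn))
    return ShiftTable(label, records)


@pytest.fixture
def toy_pdb(tmp_path):
    """Minimal two-residue PDB file (text, fixed-width)."""

    def atom(serial, name, resn, ch, resi, x, y, z, b=20.0):
        return (
            f"ATOM  {serial:5d} {name:^4s}{resn:>4s} {ch}{resi:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}          "
            f"{name.strip()[0]:>2s}"
        )

    lines = [
        atom(1, "N", "LEU", "A", 19, 1.0, 2.0, 3.0),
        atom(2, "CA", "LEU", "A", 19, 2.0, 3.0, 4.0),
        atom(3, "N", "HIS", "A", 94, 5.0, 6.0, 7.0),
        atom(4, "CA", "HIS", "A", 94, 6.0, 7.0, 8.0),
        "TER",
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
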