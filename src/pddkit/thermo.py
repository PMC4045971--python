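"""Nearest-neighbor DNA/DNA duplex thermodynamics.

Melting temperatures of probe/cDNA duplexes are estimated with the unified
nearest-neighbor model: the duplex enthalpy and entropy are sums of
dinucleotide stacking terms plus initiation terms for the two terminal base
pairs, and the two-state melting temperature follows from

    Tm = 1000 * dH / (dS_salt + R * ln(C_T / x)) - 273.15

with ``dH`` in kcal/mol, ``dS`` in cal/(mol K), ``R = 1.987`` cal/(mol K),
``C_T`` the total probe strand concentration and ``x = 4`` for a duplex of
two distinct strands.  Monovalent salt enters through the entropic
correction ``dS + 0.368 * (N - 1) * ln([Na+])``.

Only perfect-match duplexes are scored: probe/transcript matches are exact
substrings by construction, so mismatch and dangling-end terms never arise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "NNParameterTable",
    "HybridizationConditions",
    "duplex_energies",
    "melting_temperature",
    "reverse_complement",
    "GAS_CONSTANT",
]

#: Gas constant in cal/(mol K), the unit system of the parameter table.
GAS_CONSTANT = 1.987

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq[::-1].translate(_COMPLEMENT)


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor stacking and initiation parameters.

    ``stack_dH``/``stack_dS`` map each of the 16 top-strand dinucleotides to
    its enthalpy (kcal/mol) and entropy (cal/(mol K)); ``init_*`` are the
    duplex-initiation terms applied once per terminal A.T or G.C base pair.
    """

    stack_dH: dict[str, float]
    stack_dS: dict[str, float]
    init_dH_AT: float
    init_dS_AT: float
    init_dH_GC: float
    init_dS_GC: float
    source_label: str = "unified nearest-neighbor (Allawi & SantaLucia)"

    def __post_init__(self) -> None:
        expected = {a + b for a in "ACGT" for b in "ACGT"}
        for name, table in (("stack_dH", self.stack_dH), ("stack_dS", self.stack_dS)):
            missing = expected - set(table)
            if missing:
                raise ValueError(f"{name} is missing stacks: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path: str | Path, source_label: str | None = None) -> "NNParameterTable":
        """Load a table from the 3-column TSV format shipped in ``data/``."""
        stacks_h: dict[str, float] = {}
        stacks_s: dict[str, float] = {}
        init: dict[str, tuple[float, float]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("stack\t"):
                continue
            key, h, s = line.split("\t")
            if key.startswith("init_"):
                init[key] = (float(h), float(s))
            else:
                stacks_h[key] = float(h)
                stacks_s[key] = float(s)
        return cls(
            stack_dH=stacks_h,
            stack_dS=stacks_s,
            init_dH_AT=init["init_AT"][0],
            init_dS_AT=init["init_AT"][1],
            init_dH_GC=init["init_GC"][0],
            init_dS_GC=init["init_GC"][1],
            source_label=source_label or f"TSV table {path}",
        )


def _load_default_table() -> NNParameterTable:
    with resources.as_file(resources.files("pddkit.data") / "nn_unified.tsv") as p:
        return NNParameterTable.from_tsv(p, source_label="unified nearest-neighbor (Allawi & SantaLucia)")


_DEFAULT_TABLE: NNParameterTable | None = None


def default_table() -> NNParameterTable:
    """The packaged unified nearest-neighbor table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = _load_default_table()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class HybridizationConditions:
    """Solution conditions for Tm estimation.

    ``probe_concentration`` is the per-probe strand concentration C_T in
    mol/L (default 0.81 uM, the per-probe concentration of the depletion
    reaction); ``monovalent_salt`` in mol/L; ``symmetry_factor`` is 4 for
    non-self-complementary duplexes (probe and cDNA are distinct strands)
    and 1 for self-complementary ones.
    """

    probe_concentration: float = 8.1e-7
    monovalent_salt: float = 0.05
    symmetry_factor: int = 4

    def __post_init__(self) -> None:
        if self.probe_concentration <= 0:
            raise ValueError("probe_concentration must be > 0")
        if self.monovalent_salt <= 0:
            raise ValueError("monovalent_salt must be > 0")
        if self.symmetry_factor not in (1, 4):
            raise ValueError("symmetry_factor must be 1 or 4")


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("duplex must be at least 2 nt long")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"ambiguous or non-DNA bases not allowed: {sorted(bad)}")
    return seq


def duplex_energies(
    sequence: str, table: NNParameterTable | None = None
) -> tuple[float, float]:
    """Total (dH, dS) of the perfect duplex formed by ``sequence``.

    Returns enthalpy in kcal/mol and entropy in cal/(mol K): the sum of the
    stacking terms over consecutive dinucleotides plus one initiation term
    per terminal base pair.
    """
    seq = _check_sequence(sequence)
    table = table or default_table()
    dH = sum(table.stack_dH[seq[i : i + 2]] for i in range(len(seq) - 1))
    dS = sum(table.stack_dS[seq[i : i + 2]] for i in range(len(seq) - 1))
    for terminal in (seq[0], seq[-1]):
        if terminal in "AT":
            dH += table.init_dH_AT
            dS += table.init_dS_AT
        else:
            dH += table.init_dH_GC
            dS += table.init_dS_GC
    return dH, dS


def melting_temperature(
    sequence: str,
    conditions: HybridizationConditions | None = None,
    table: NNParameterTable | None = None,
) -> float:
    """Two-state melting temperature in degrees Celsius.

    Applies the entropic monovalent-salt correction
    ``dS + 0.368 * (N - 1) * ln([Na+])`` before the concentration term.
    Raises ``ValueError`` on a non-negative denominator rather than
    returning NaN.
    """
    cond = conditions or HybridizationConditions()
    dH, dS = duplex_energies(sequence, table)
    n = len(sequence)
    dS_corr = dS + 0.368 * (n - 1) * math.log(cond.monovalent_salt)
    denom = dS_corr + GAS_CONSTANT * math.log(
        cond.probe_concentration / cond.symmetry_factor
    )
    if denom >= 0:
        raise ValueError(
            "non-negative Tm denominator; duplex/conditions are outside the "
            "two-state model's domain"
        )
    return 1000.0 * dH / denom - 273.15


def stability_free_energy(
    sequence: str,
    celsius: float = 48.0,
    conditions: HybridizationConditions | None = None,
    table: NNParameterTable | None = None,
) -> float:
    """Duplex dG at a given temperature (kcal/mol), with salt correction."""
    cond = conditions or HybridizationConditions()
    dH, dS = duplex_energies(sequence, table)
    dS_corr = dS + 0.368 * (len(sequence) - 1) * math.log(cond.monovalent_salt)
    t_kelvin = celsius + 273.15
    return dH - t_kelvin * dS_corr / 1000.0
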