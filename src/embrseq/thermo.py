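"""Nearest-neighbor duplex melting temperatures for DNA oligos.

The melting temperature of a primer/target duplex is computed from the unified
nearest-neighbor parameter set (dinucleotide stack enthalpies and entropies
with duplex-initiation terms and a symmetry correction), an entropy-based
monovalent-salt correction, and the two-state relation

    Tm = dH / (dS_salt + R ln(C_T / x)) - 273.15

with dH in cal/mol, dS in cal/(mol K), R = 1.987 cal/(mol K), total strand
concentration C_T, and x = 4 for non-self-complementary duplexes (x = 1 for
self-complementary ones).  The salt correction is

    dS_salt = dS + 0.368 (N - 1) ln [Na+]

with N the oligo length and [Na+] the monovalent cation molarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from embrseq.reference import revcomp

R_GAS = 1.987  # cal / (mol K)

# Unified DNA/DNA stack parameters: dinucleotide (5'->3' on one strand) ->
# (dH kcal/mol, dS cal/(mol K)).  A stack and its reverse complement share one
# physical duplex, hence identical values.
_UNIFIED_STACKS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

# Duplex initiation per terminal base pair.
_INIT_GC = (0.1, -2.8)   # terminal G·C
_INIT_AT = (2.3, 4.1)    # terminal A·T
_SYMMETRY = (0.0, -1.4)  # self-complementary duplexes

PARAMETER_SETS = {"unified": _UNIFIED_STACKS}


@dataclass(frozen=True)
class ThermoConditions:
    """Hybridization conditions for Tm calculation.

    monovalent_salt in mM (default 50), oligo_conc is total strand
    concentration C_T in nM (default 250), parameter_set names the
    nearest-neighbor table.
    """

    monovalent_salt: float = 50.0
    oligo_conc: float = 250.0
    parameter_set: str = "unified"

    def __post_init__(self) -> None:
        if self.monovalent_salt <= 0:
            raise ValueError("monovalent_salt must be > 0 mM")
        if self.oligo_conc <= 0:
            raise ValueError("oligo_conc must be > 0 nM")
        if self.parameter_set not in PARAMETER_SETS:
            raise ValueError(f"unknown parameter_set {self.parameter_set!r}")


DEFAULT_CONDITIONS = ThermoConditions()


def duplex_dh_ds(seq: str, parameter_set: str = "unified") -> tuple[float, float]:
    """Sum stack + initiation (+ symmetry) terms. Returns (dH kcal/mol, dS cal/mol/K)."""
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("duplex requires at least 2 bases")
    table = PARAMETER_SETS[parameter_set]
    if not set(seq) <= set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"sequence contains non-ACGT symbols (ambiguity codes unsupported): {bad}")
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = table[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s
    if seq == revcomp(seq):
        dh += _SYMMETRY[0]
        ds += _SYMMETRY[1]
    return dh, ds


def tm_nearest_neighbor(seq: str, cond: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    """Nearest-neighbor melting temperature of ``seq`` against its perfect complement, in °C.

    Raises ValueError for sequences shorter than 8 nt or containing
    ambiguity codes.
    """
    if len(seq) < 8:
        raise ValueError(f"sequence too short for a meaningful duplex Tm ({len(seq)} < 8 nt)")
    dh, ds = duplex_dh_ds(seq, cond.parameter_set)
    na_molar = cond.monovalent_salt * 1e-3
    ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(na_molar)
    ct_molar = cond.oligo_conc * 1e-9
    x = 1.0 if seq.upper() == revcomp(seq.upper()) else 4.0
    tm_kelvin = dh * 1000.0 / (ds_salt + R_GAS * math.log(ct_molar / x))
    return tm_kelvin - 273.15
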