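"""Melting-temperature computation for primers and the overlap duplex.

The workhorse is the nearest-neighbor (NN) thermodynamic model: Tm is
obtained from summed dinucleotide-stack enthalpies and entropies with
initiation and terminal corrections, then salt-corrected for the reaction's
ionic conditions.  The default parameterization is the unified
Allawi & SantaLucia set with an entropic salt correction at 50 mM monovalent
cation and 25 nM of each strand — the defaults of Biopython's ``Tm_NN``
routine, to which this module delegates.  Every constant is configurable
through :class:`ThermoConditions` so other dialects can be matched.

A Wallace-rule estimate (2 degC per A/T, 4 degC per G/C) is provided as a
quick integer-arithmetic sanity fallback; it is not used for ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from .errors import ThermoError

logger = logging.getLogger(__name__)

#: minimum primer length for the NN model; shorter duplexes are dominated by
#: end effects and the model is unreliable.
MIN_NN_LENGTH = 8

#: published NN parameter tables, by first author and year.
NN_TABLES = {
    "breslauer1986": _mt.DNA_NN1,
    "sugimoto1996": _mt.DNA_NN2,
    "allawi1997": _mt.DNA_NN3,   # unified set; Biopython default
    "santalucia2004": _mt.DNA_NN4,
}

TM_METHODS = ("nearest_neighbor", "wallace")


@dataclass(frozen=True)
class ThermoConditions:
    """Ionic and strand-concentration context for Tm computation.

    Parameters
    ----------
    monovalent_cation_mM : float
        Na+/K+ concentration in mM (default 50).
    primer_concentration_nM : float
        Concentration of each strand in nM (default 25 each).
    divalent_cation_mM, dNTP_mM : float
        Mg2+ and dNTP concentrations in mM (default 0; dNTPs chelate Mg2+).
    salt_correction : int
        Salt-correction method index, 0 (none) through 7, following the
        numbering of Biopython's ``MeltingTemp.salt_correction``.  The
        default, 5, applies the entropic correction
        dS += 0.368 x (N-1) x ln[Na+].
    nn_table : str
        One of ``breslauer1986``, ``sugimoto1996``, ``allawi1997`` (default),
        ``santalucia2004``.
    method : str
        ``nearest_neighbor`` (default) or ``wallace``.
    """

    monovalent_cation_mM: float = 50.0
    primer_concentration_nM: float = 25.0
    divalent_cation_mM: float = 0.0
    dNTP_mM: float = 0.0
    salt_correction: int = 5
    nn_table: str = "allawi1997"
    method: str = "nearest_neighbor"

    def __post_init__(self) -> None:
        for name in ("monovalent_cation_mM", "primer_concentration_nM",
                     "divalent_cation_mM", "dNTP_mM"):
            if getattr(self, name) < 0:
                raise ThermoError(f"{name} must be >= 0")
        if self.salt_correction not in range(0, 8):
            raise ThermoError("salt_correction must be an integer in 0..7")
        if self.nn_table not in NN_TABLES:
            raise ThermoError(
                f"unknown nn_table {self.nn_table!r}; choose from {sorted(NN_TABLES)}"
            )
        if self.method not in TM_METHODS:
            raise ThermoError(f"method must be one of {TM_METHODS}")
        if self.salt_correction != 0 and self.monovalent_cation_mM <= 0:
            raise ThermoError(
                "monovalent_cation_mM must be > 0 when a salt correction is applied"
            )


DEFAULT_CONDITIONS = ThermoConditions()


def tm_nearest_neighbor(s: str, cond: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    """Nearest-neighbor Tm (degC) of ``s`` against its perfect complement.

    Assumes a non-self-complementary duplex of ``s`` with its exact reverse
    complement at the strand concentrations in ``cond``.  Deterministic for
    fixed inputs.  Values outside 0-120 degC are allowed but logged, as they
    are implausible for primer-length inputs.
    """
    if len(s) < MIN_NN_LENGTH:
        raise ThermoError(
            f"sequence of length {len(s)} is too short for the NN model "
            f"(minimum {MIN_NN_LENGTH} nt)"
        )
    tm = _mt.Tm_NN(
        s,
        nn_table=NN_TABLES[cond.nn_table],
        Na=cond.monovalent_cation_mM,
        Mg=cond.divalent_cation_mM,
        dNTPs=cond.dNTP_mM,
        dnac1=cond.primer_concentration_nM,
        dnac2=cond.primer_concentration_nM,
        saltcorr=cond.salt_correction,
        selfcomp=False,
    )
    if not 0.0 <= tm <= 120.0:
        logger.warning("NN Tm %.1f degC for %r is outside the plausible 0-120 range", tm, s)
    return float(tm)


def tm_wallace(s: str) -> int:
    """Wallace-rule Tm: 2 degC per A/T plus 4 degC per G/C, exact integer."""
    gc = s.count("G") + s.count("C")
    return 2 * (len(s) - gc) + 4 * gc


def melting_temperature(s: str, cond: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    """Tm of ``s`` using the method selected in ``cond``."""
    if cond.method == "wallace":
        return float(tm_wallace(s))
    return tm_nearest_neighbor(s, cond)
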