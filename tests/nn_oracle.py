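"""Independent nearest-neighbor Tm oracle for the test suite.

A from-scratch dH/dS summation over the published unified nearest-neighbor
parameter set (Allawi & SantaLucia 1997), with terminal initiation terms,
the entropic salt correction dS += 0.368 (N-1) ln[Na+], and the two-state
Tm formula for a non-self-complementary duplex.  Typed directly from the
published table; deliberately independent of the package's thermo module.
"""

import math

# stack -> (dH kcal/mol, dS cal/mol/K); the ten unique Watson-Crick stacks
UNIFIED_NN = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
INIT_AT = (2.3, 4.1)    # per terminal A-T pair
INIT_GC = (0.1, -2.8)   # per terminal G-C pair

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
R_GAS = 1.987  # cal/(mol*K)


def _stack(dimer: str) -> tuple[float, float]:
    if dimer in UNIFIED_NN:
        return UNIFIED_NN[dimer]
    # a stack read from the complementary strand has identical parameters
    return UNIFIED_NN[_COMP[dimer[1]] + _COMP[dimer[0]]]


def tm_oracle(seq: str, na_mM: float = 50.0,
              dnac1_nM: float = 25.0, dnac2_nM: float = 25.0) -> float:
    """Tm (degC) of ``seq`` vs its perfect complement, brute-force summation."""
    dh = ds = 0.0
    for terminal in (seq[0], seq[-1]):
        init = INIT_AT if terminal in "AT" else INIT_GC
        dh += init[0]
        ds += init[1]
    for a, b in zip(seq, seq[1:]):
        sh, ss = _stack(a + b)
        dh += sh
        ds += ss
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    k_conc = (dnac1_nM - dnac2_nM / 2.0) * 1e-9
    return 1000.0 * dh / (ds + R_GAS * math.log(k_conc)) - 273.15
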