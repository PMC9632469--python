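"""Enumerate, score, and rank primer tetrads for SOE-PCR ligation.

A tetrad consists of:

* ``gene_5`` — forward end primer, the first ``n5`` bases of the chimera;
* ``overlap_3`` — reverse junction primer spanning the junction, carrying
  ``q1`` bases of fragment 1 under its 3' end and a ``q2``-base 5' tail
  from fragment 2 (antisense orientation);
* ``overlap_5`` — forward junction primer with ``p1`` bases from the 3' end
  of fragment 1 and ``p2`` bases from the 5' end of fragment 2;
* ``gene_3`` — reverse end primer, the reverse complement of the last
  ``n3`` chimera bases.

The two junction primers are partially reverse-complementary: they share a
duplex (the "overlap region") of ``min(p1,q1) + min(p2,q2)`` bases centred
on the junction, each protruding as a 3' overhang into the partner
fragment.  Part lengths are a fixed base extended by per-part offsets
i, j, k, l that each range over 0..3 by default, giving 16 forward x 16
reverse junction primers; end-primer lengths range over 14..30 (17 choices
each), for 16 x 16 x 17 x 17 = 73,984 tetrads at the defaults.

Each tetrad is scored by the Tm-balance statistic

    K = 100 x ( |Tm_g5 - Tm_o3| + |Tm_o5 - Tm_g3| + |Tm_g5 - Tm_g3|
              + |(Tm_g5+Tm_g3)/2 - Tm_ov - 3| + |Tm_ov - Tm_fav|
              + |(Tm_g5+Tm_g3)/2 - Tm_fav| )

where Tm_ov is the Tm of the overlap duplex and Tm_fav the preferred
duplex Tm (63 degC by default).  Lower K means a better-balanced tetrad;
the triangle inequality on the last three terms gives K >= 300 always.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from . import seqio
from .errors import ConfigError, DesignError
from .seqio import FragmentPair, gc_percent, reverse_complement
from .thermo import ThermoConditions, DEFAULT_CONDITIONS, melting_temperature


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of the tetrad search.

    ``tm_favorite`` is the preferred overlap-duplex Tm in degC.  End primers
    are searched over lengths ``end_len_min..end_len_max``.  Junction-primer
    part lengths are ``<base> + offset`` with offsets in
    ``offset_min..offset_max``: ``fwd_frag1_base + i`` / ``fwd_frag2_base + j``
    for the forward junction primer, ``rev_frag1_base + k`` /
    ``rev_frag2_base + l`` for the reverse one.
    """

    tm_favorite: float = 63.0
    end_len_min: int = 14
    end_len_max: int = 30
    offset_min: int = 0
    offset_max: int = 3
    fwd_frag1_base: int = 8
    fwd_frag2_base: int = 12
    rev_frag1_base: int = 12
    rev_frag2_base: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.offset_min <= self.offset_max:
            raise ConfigError("need 0 <= offset_min <= offset_max")
        if not 1 <= self.end_len_min <= self.end_len_max:
            raise ConfigError("need 1 <= end_len_min <= end_len_max")
        for name in ("fwd_frag1_base", "fwd_frag2_base",
                     "rev_frag1_base", "rev_frag2_base"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        # Both junction primers must stay 3'-recessed relative to each other
        # for every offset combination, so each has a 3' overhang (or is
        # flush) and the duplex is well defined.
        if self.rev_frag1_base + self.offset_min < self.fwd_frag1_base + self.offset_max:
            raise ConfigError(
                "rev_frag1_base + offset_min must be >= fwd_frag1_base + offset_max "
                "(reverse junction primer would be 5'-recessed on fragment 1)"
            )
        if self.fwd_frag2_base + self.offset_min < self.rev_frag2_base + self.offset_max:
            raise ConfigError(
                "fwd_frag2_base + offset_min must be >= rev_frag2_base + offset_max "
                "(forward junction primer would be 5'-recessed on fragment 2)"
            )

    @property
    def offset_span(self) -> int:
        return self.offset_max - self.offset_min + 1

    @property
    def end_span(self) -> int:
        return self.end_len_max - self.end_len_min + 1

    @property
    def n_combinations(self) -> int:
        """Total tetrads: (offset_span^2)^2 x end_span^2."""
        return (self.offset_span ** 2) ** 2 * self.end_span ** 2


DEFAULT_CONFIG = DesignConfig()


@dataclass(frozen=True)
class OverlapPrimerParams:
    """Part lengths of one junction-primer pair.

    ``p1``/``p2``: fragment-1/fragment-2 parts of the forward junction
    primer; ``q1``/``q2``: the same for the reverse junction primer
    (measured on the sense strand under the primer).  ``i, j, k, l`` are the
    offsets that produced them.
    """

    p1: int
    p2: int
    q1: int
    q2: int
    i: int
    j: int
    k: int
    l: int

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.q1, self.q2) < 1:
            raise ConfigError("junction-primer part lengths must be >= 1")
        if self.q1 < self.p1 or self.p2 < self.q2:
            raise ConfigError(
                "junction primers must be 3'-recessed, never 5'-recessed: "
                f"need q1 >= p1 and p2 >= q2, got p1={self.p1} p2={self.p2} "
                f"q1={self.q1} q2={self.q2}"
            )

    @property
    def offset_sum(self) -> int:
        return self.i + self.j + self.k + self.l


@dataclass(frozen=True)
class PrimerCandidate:
    """One primer with its per-primer report statistics."""

    role: str  # gene_5 | overlap_3 | overlap_5 | gene_3
    sequence: str
    length: int
    gc: float
    tm: float


@dataclass(frozen=True)
class PrimerCombination:
    """One scored tetrad plus its overlap duplex."""

    gene_5: PrimerCandidate
    overlap_3: PrimerCandidate
    overlap_5: PrimerCandidate
    gene_3: PrimerCandidate
    overlap_region: str
    overlap_tm: float
    k_score: float
    params: OverlapPrimerParams
    n5: int
    n3: int

    @property
    def k_display(self) -> int:
        """K rounded to the nearest integer, as reported."""
        return round(self.k_score)

    @property
    def primers(self) -> tuple[PrimerCandidate, ...]:
        """Report order: gene_5, overlap_3, overlap_5, gene_3."""
        return (self.gene_5, self.overlap_3, self.overlap_5, self.gene_3)

    @property
    def sort_key(self) -> tuple:
        p = self.params
        return (self.k_score, p.offset_sum, self.n5, self.n3, p.i, p.j, p.k, p.l)


def make_overlap_forward(pair: FragmentPair, p1: int, p2: int) -> str:
    """Forward junction primer: last ``p1`` bases of fragment 1 followed by
    the first ``p2`` bases of fragment 2, on the sense strand."""
    J = pair.junction
    if not 1 <= p1 <= J:
        raise DesignError(f"p1={p1} out of range 1..{J}")
    if not 1 <= p2 <= len(pair.second):
        raise DesignError(f"p2={p2} out of range 1..{len(pair.second)}")
    return pair.chimera[J - p1: J + p2]


def make_overlap_reverse(pair: FragmentPair, q1: int, q2: int) -> str:
    """Reverse junction primer: reverse complement of the sense-strand window
    covering the last ``q1`` bases of fragment 1 and first ``q2`` of fragment 2."""
    J = pair.junction
    if not 1 <= q1 <= J:
        raise DesignError(f"q1={q1} out of range 1..{J}")
    if not 1 <= q2 <= len(pair.second):
        raise DesignError(f"q2={q2} out of range 1..{len(pair.second)}")
    return reverse_complement(pair.chimera[J - q1: J + q2])


def make_end_primers(pair: FragmentPair, n5: int, n3: int,
                     cfg: DesignConfig = DEFAULT_CONFIG) -> tuple[str, str]:
    """End primers for the full-length chimera: the first ``n5`` bases
    (gene_5) and the reverse complement of the last ``n3`` bases (gene_3)."""
    J, L = pair.junction, len(pair.chimera)
    for n, label in ((n5, "n5"), (n3, "n3")):
        if not cfg.end_len_min <= n <= cfg.end_len_max:
            raise DesignError(
                f"{label}={n} outside configured range "
                f"{cfg.end_len_min}..{cfg.end_len_max}"
            )
    if n5 > J:
        raise DesignError(f"n5={n5} exceeds fragment 1 length {J}")
    if n3 > len(pair.second):
        raise DesignError(f"n3={n3} exceeds fragment 2 length {len(pair.second)}")
    return pair.chimera[:n5], reverse_complement(pair.chimera[L - n3:])


def overlap_duplex(pair: FragmentPair, params: OverlapPrimerParams) -> str:
    """The duplex shared by the two junction primers, on the sense strand:
    ``chimera[J - min(p1,q1) : J + min(p2,q2)]``."""
    J = pair.junction
    return pair.chimera[J - min(params.p1, params.q1): J + min(params.p2, params.q2)]


def k_score(tm_gene5: float, tm_overlap3: float, tm_overlap5: float,
            tm_gene3: float, tm_overlap: float, tm_favorite: float) -> float:
    """Tm-balance statistic K of one tetrad (full precision; lower is better)."""
    mean_end = (tm_gene5 + tm_gene3) / 2
    return 100 * (
        abs(tm_gene5 - tm_overlap3)
        + abs(tm_overlap5 - tm_gene3)
        + abs(tm_gene5 - tm_gene3)
        + abs(mean_end - tm_overlap - 3)
        + abs(tm_overlap - tm_favorite)
        + abs(mean_end - tm_favorite)
    )


def iter_overlap_params(cfg: DesignConfig = DEFAULT_CONFIG) -> Iterator[OverlapPrimerParams]:
    """All (i, j, k, l) offset combinations as junction-primer part lengths."""
    offsets = range(cfg.offset_min, cfg.offset_max + 1)
    for i in offsets:
        for j in offsets:
            for k in offsets:
                for l in offsets:
                    yield OverlapPrimerParams(
                        p1=cfg.fwd_frag1_base + i, p2=cfg.fwd_frag2_base + j,
                        q1=cfg.rev_frag1_base + k, q2=cfg.rev_frag2_base + l,
                        i=i, j=j, k=k, l=l,
                    )


def _check_lengths(pair: FragmentPair, cfg: DesignConfig) -> None:
    need1 = max(cfg.end_len_max, cfg.rev_frag1_base + cfg.offset_max)
    need2 = max(cfg.end_len_max, cfg.fwd_frag2_base + cfg.offset_max)
    if pair.junction < need1:
        raise DesignError(
            f"fragment 1 is {pair.junction} nt but the configuration needs {need1}"
        )
    if len(pair.second) < need2:
        raise DesignError(
            f"fragment 2 is {len(pair.second)} nt but the configuration needs {need2}"
        )


def enumerate_tetrads(pair: FragmentPair, cfg: DesignConfig = DEFAULT_CONFIG,
                      cond: ThermoConditions = DEFAULT_CONDITIONS) -> list[PrimerCombination]:
    """Build, score, and rank every primer tetrad for ``pair``.

    Returns exactly ``cfg.n_combinations`` fully populated combinations,
    sorted ascending by K with the deterministic tie-break of :func:`rank`.
    Tm values are memoized per distinct sequence, so the cost is dominated
    by the combinatorial scoring loop, not thermodynamics.
    """
    _check_lengths(pair, cfg)
    J = pair.junction

    tm_cache: dict[str, float] = {}

    def tm_of(seq: str) -> float:
        t = tm_cache.get(seq)
        if t is None:
            t = melting_temperature(seq, cond)
            tm_cache[seq] = t
        return t

    def candidate(role: str, seq: str) -> PrimerCandidate:
        return PrimerCandidate(role=role, sequence=seq, length=len(seq),
                               gc=gc_percent(seq), tm=tm_of(seq))

    end_lengths = range(cfg.end_len_min, cfg.end_len_max + 1)
    gene5s = {}
    gene3s = {}
    for n in end_lengths:
        g5_seq, g3_seq = make_end_primers(pair, n, n, cfg)
        gene5s[n] = candidate("gene_5", g5_seq)
        gene3s[n] = candidate("gene_3", g3_seq)

    offsets = range(cfg.offset_min, cfg.offset_max + 1)
    fwds = []
    for i in offsets:
        for j in offsets:
            p1, p2 = cfg.fwd_frag1_base + i, cfg.fwd_frag2_base + j
            fwds.append((i, j, p1, p2, candidate("overlap_5", make_overlap_forward(pair, p1, p2))))
    revs = []
    for k in offsets:
        for l in offsets:
            q1, q2 = cfg.rev_frag1_base + k, cfg.rev_frag2_base + l
            revs.append((k, l, q1, q2, candidate("overlap_3", make_overlap_reverse(pair, q1, q2))))

    duplex_cache: dict[tuple[int, int], tuple[str, float]] = {}
    combos: list[PrimerCombination] = []
    favorite = cfg.tm_favorite
    for i, j, p1, p2, fwd in fwds:
        for k, l, q1, q2, rev in revs:
            d1, d2 = min(p1, q1), min(p2, q2)
            cached = duplex_cache.get((d1, d2))
            if cached is None:
                dup_seq = pair.chimera[J - d1: J + d2]
                cached = (dup_seq, tm_of(dup_seq))
                duplex_cache[(d1, d2)] = cached
            dup_seq, dup_tm = cached
            params = OverlapPrimerParams(p1=p1, p2=p2, q1=q1, q2=q2, i=i, j=j, k=k, l=l)
            for n5 in end_lengths:
                g5 = gene5s[n5]
                for n3 in end_lengths:
                    g3 = gene3s[n3]
                    combos.append(PrimerCombination(
                        gene_5=g5, overlap_3=rev, overlap_5=fwd, gene_3=g3,
                        overlap_region=dup_seq, overlap_tm=dup_tm,
                        k_score=k_score(g5.tm, rev.tm, fwd.tm, g3.tm, dup_tm, favorite),
                        params=params, n5=n5, n3=n3,
                    ))
    return rank(combos)


def rank(combinations: list[PrimerCombination]) -> list[PrimerCombination]:
    """Sort tetrads ascending by K; ties broken by offset sum i+j+k+l, then
    n5, then n3, then the individual offsets — stable across runs."""
    if not combinations:
        raise DesignError("no primer combinations to rank")
    return sorted(combinations, key=lambda c: c.sort_key)
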