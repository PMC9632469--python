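"""In-silico verification of a primer tetrad: the three SOE-PCR reactions.

Reaction 1 amplifies fragment 1 with gene_5 + overlap_3; reaction 2
amplifies fragment 2 with overlap_5 + gene_3.  The two products share the
junction duplex, so in reaction 3 they prime each other across that bridge
and extend into the full-length chimera — optionally followed by
amplification with the end primers gene_5/gene_3 (both fusion routes yield
the same sequence).

Annealing is modelled as exact 3'-anchored matching: a primer binds wherever
its 3'-terminal ``min_anneal`` or more bases match a template strand
exactly; any unmatched 5' remainder is carried as a tail and incorporated
into the product, which is how the junction primers import sequence from the
partner fragment.  A primer with zero or multiple sites fails the reaction —
conservative, because multiple priming sites would smear a real SOE-PCR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .design import PrimerCombination
from .errors import AmplificationError
from .seqio import FragmentPair, reverse_complement

DEFAULT_MIN_ANNEAL = 10
DEFAULT_MIN_BRIDGE = 10


@dataclass(frozen=True)
class Template:
    """A double-stranded PCR template, represented by its sense strand."""

    sense: str


@dataclass(frozen=True)
class AnnealingSite:
    """One primer binding site.

    ``strand`` names the template strand whose 5'->3' sequence contains the
    primer's 3'-terminal match (i.e. the strand the primer's extension
    product copies).  ``start``/``end`` delimit the matched bases in
    sense-strand coordinates, 0-based half-open.  ``matched_len`` is the
    length of the maximal 3'-terminal exact match; ``tail_len`` the
    unmatched 5' remainder, so ``matched_len + tail_len`` is the primer
    length.
    """

    strand: str  # "sense" | "antisense"
    start: int
    end: int
    matched_len: int
    tail_len: int


@dataclass(frozen=True)
class Amplicon:
    """A simulated PCR product: its sense strand and the two priming sites."""

    sense: str
    fwd_site: AnnealingSite
    rev_site: AnnealingSite


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start indices of needle in haystack."""
    hits, pos = [], haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def find_annealing_sites(template: Template, primer: str,
                         min_anneal: int = DEFAULT_MIN_ANNEAL) -> list[AnnealingSite]:
    """All sites where the primer's 3' end matches either strand exactly.

    For each occurrence of the primer's 3'-terminal ``min_anneal``-mer the
    match is extended toward the primer's 5' end as far as it stays exact,
    and the maximal match is reported.
    """
    if min_anneal < 6:
        raise AmplificationError("min_anneal must be >= 6")
    if len(primer) < min_anneal:
        return []
    anchor = primer[-min_anneal:]
    L = len(template.sense)
    sites = []
    for strand in ("sense", "antisense"):
        strand_seq = template.sense if strand == "sense" else reverse_complement(template.sense)
        for hit in _occurrences(strand_seq, anchor):
            end = hit + min_anneal            # strand coords, exclusive
            matched = min_anneal
            start = hit
            while (matched < len(primer) and start > 0
                   and strand_seq[start - 1] == primer[-(matched + 1)]):
                start -= 1
                matched += 1
            if strand == "sense":
                s, e = start, end
            else:
                s, e = L - end, L - start
            sites.append(AnnealingSite(strand=strand, start=s, end=e,
                                       matched_len=matched,
                                       tail_len=len(primer) - matched))
    return sites


def _unique_site(template: Template, primer: str, role: str,
                 min_anneal: int) -> AnnealingSite:
    sites = find_annealing_sites(template, primer, min_anneal)
    if not sites:
        raise AmplificationError(f"primer {role} does not anneal")
    if len(sites) > 1:
        where = ", ".join(f"{s.strand}:{s.start}-{s.end}" for s in sites)
        raise AmplificationError(f"ambiguous priming for {role}: sites at {where}")
    return sites[0]


def amplify(template: Template, fwd: str, rev: str,
            min_anneal: int = DEFAULT_MIN_ANNEAL) -> Amplicon:
    """Simulate one PCR: exactly one convergent site per primer required.

    The product is the forward primer's 5' tail, the sense-strand span from
    the forward match through the reverse match, then the reverse complement
    of the reverse primer's 5' tail — so it begins with the forward primer
    and ends with the reverse complement of the reverse primer.
    """
    fsite = _unique_site(template, fwd, "forward", min_anneal)
    rsite = _unique_site(template, rev, "reverse", min_anneal)
    if fsite.strand == rsite.strand:
        raise AmplificationError(
            "no product: primers bind the same strand (divergent orientation)"
        )
    if fsite.strand != "sense":
        raise AmplificationError(
            "no product: forward primer binds the antisense orientation; "
            "swap the primer roles"
        )
    if not (fsite.start <= rsite.start and fsite.end <= rsite.end):
        raise AmplificationError("no product: primer sites are divergent")
    fwd_tail = fwd[:fsite.tail_len]
    rev_tail = rev[:rsite.tail_len]
    sense = fwd_tail + template.sense[fsite.start: rsite.end] + reverse_complement(rev_tail)
    return Amplicon(sense=sense, fwd_site=fsite, rev_site=rsite)


def overlap_extend(upstream: Amplicon | str, downstream: Amplicon | str,
                   min_bridge: int = DEFAULT_MIN_BRIDGE) -> str:
    """Fuse two products through their shared junction duplex.

    Denatured strands re-anneal where a suffix of the upstream product
    equals a prefix of the downstream product; the recessed 3' ends of that
    duplex are extended by the polymerase, yielding
    ``upstream + downstream[bridge:]``.  The maximal exact suffix-prefix
    match of length >= ``min_bridge`` is used.
    """
    if min_bridge < 10:
        raise AmplificationError("min_bridge must be >= 10")
    up = upstream.sense if isinstance(upstream, Amplicon) else upstream
    down = downstream.sense if isinstance(downstream, Amplicon) else downstream
    for t in range(min(len(up), len(down)), min_bridge - 1, -1):
        if up[-t:] == down[:t]:
            return up + down[t:]
    raise AmplificationError(
        f"fragments do not overlap (no exact suffix/prefix bridge >= {min_bridge} nt)"
    )


@dataclass
class VerificationReport:
    """Structured outcome of simulating the three reactions for one tetrad."""

    passed: bool = False
    with_end_primers: bool = True
    steps: list[dict] = field(default_factory=list)
    reconstruction: Optional[str] = None

    def add_step(self, name: str, ok: bool, detail: str,
                 product_length: Optional[int] = None) -> None:
        self.steps.append({"name": name, "ok": ok, "detail": detail,
                           "product_length": product_length})

    @property
    def failures(self) -> list[dict]:
        return [s for s in self.steps if not s["ok"]]

    def to_json(self) -> str:
        return json.dumps({
            "passed": self.passed,
            "with_end_primers": self.with_end_primers,
            "steps": self.steps,
            "reconstruction_length":
                None if self.reconstruction is None else len(self.reconstruction),
        }, indent=2)

    def to_text(self) -> str:
        lines = [f"verification: {'PASS' if self.passed else 'FAIL'} "
                 f"({'with' if self.with_end_primers else 'without'} end primers)"]
        for s in self.steps:
            mark = "ok" if s["ok"] else "FAIL"
            size = f", {s['product_length']} bp" if s["product_length"] else ""
            lines.append(f"  [{mark}] {s['name']}: {s['detail']}{size}")
        return "\n".join(lines)


def verify_design(pair: FragmentPair, combo: PrimerCombination,
                  with_end_primers: bool = True,
                  min_anneal: int = DEFAULT_MIN_ANNEAL,
                  min_bridge: int = DEFAULT_MIN_BRIDGE) -> VerificationReport:
    """Run the three reactions for one tetrad and compare against the chimera.

    Passes iff the reconstructed full-length sequence equals
    ``pair.chimera`` exactly.  Reaction failures are recorded as structured
    entries, not raised.
    """
    report = VerificationReport(with_end_primers=with_end_primers)
    g5 = combo.gene_5.sequence
    o3 = combo.overlap_3.sequence
    o5 = combo.overlap_5.sequence
    g3 = combo.gene_3.sequence

    try:
        up = amplify(Template(pair.first.sequence), g5, o3, min_anneal)
        report.add_step("PCR1 (gene_5 + overlap_3 on fragment 1)", True,
                        "upstream product", len(up.sense))
    except AmplificationError as exc:
        report.add_step("PCR1 (gene_5 + overlap_3 on fragment 1)", False, str(exc))
        return report

    try:
        down = amplify(Template(pair.second.sequence), o5, g3, min_anneal)
        report.add_step("PCR2 (overlap_5 + gene_3 on fragment 2)", True,
                        "downstream product", len(down.sense))
    except AmplificationError as exc:
        report.add_step("PCR2 (overlap_5 + gene_3 on fragment 2)", False, str(exc))
        return report

    try:
        fused = overlap_extend(up, down, min_bridge)
        report.add_step("overlap extension (bridge anneal + fill-in)", True,
                        "fused product", len(fused))
    except AmplificationError as exc:
        report.add_step("overlap extension (bridge anneal + fill-in)", False, str(exc))
        return report

    if with_end_primers:
        try:
            final = amplify(Template(fused), g5, g3, min_anneal)
            fused = final.sense
            report.add_step("PCR3 (gene_5 + gene_3 on fused product)", True,
                            "full-length amplification", len(fused))
        except AmplificationError as exc:
            report.add_step("PCR3 (gene_5 + gene_3 on fused product)", False, str(exc))
            return report

    report.reconstruction = fused
    ok = fused == pair.chimera
    report.add_step("reconstruction equals fragment1 + fragment2", ok,
                    "exact match" if ok else
                    f"mismatch: got {len(fused)} bp, expected {len(pair.chimera)} bp",
                    len(fused))
    report.passed = ok
    return report
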