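"""Seeded synthetic fragment-pair generator.

Produces reproducible random fragment pairs so the whole pipeline —
enumeration, scoring, report writing, in-silico verification — is testable
without downloading real gene sequences.  Fragments have an exact G+C
count (the requested fraction rounded to the nearest base), an optional
motif planted across the junction, and, by default, unique priming anchors:
every decamer a candidate primer's 3' end could sit on occurs exactly once
across both strands of the chimera, so in-silico PCR on generated pairs is
never ambiguous (mirroring the unique-sequence genes SOE-PCR is used on).
No codon structure or other real-gene mimicry is attempted.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .design import DesignConfig, DEFAULT_CONFIG
from .errors import ConfigError
from .seqio import (FragmentPair, FragmentRecord, MIN_FRAGMENT_LEN,
                    clean_sequence, reverse_complement, write_fragment)

#: decamer anchors are what the in-silico PCR keys annealing on
ANCHOR_LEN = 10

DEFAULT_SEED = 42


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fragment pair."""

    len1: int = 300
    len2: int = 300
    gc_target: float = 0.5
    seed: int = DEFAULT_SEED
    junction_motif: str | None = None
    unique_priming: bool = True

    def __post_init__(self) -> None:
        if self.len1 < MIN_FRAGMENT_LEN or self.len2 < MIN_FRAGMENT_LEN:
            raise ConfigError(f"fragment lengths must be >= {MIN_FRAGMENT_LEN}")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ConfigError("gc_target must be in [0, 1]")
        if self.junction_motif is not None:
            motif = clean_sequence(self.junction_motif)
            if len(motif) > self.len1 + self.len2:
                raise ConfigError("junction motif longer than the chimera")
            object.__setattr__(self, "junction_motif", motif)


def _random_fragment(rng: random.Random, length: int, gc_target: float) -> str:
    """Sequence with exactly round(gc_target * length) G/C bases, shuffled."""
    n_gc = round(gc_target * length)
    bases = [rng.choice("GC") for _ in range(n_gc)]
    bases += [rng.choice("AT") for _ in range(length - n_gc)]
    rng.shuffle(bases)
    return "".join(bases)


def _anchor_windows(chimera: str, junction: int, cfg: DesignConfig) -> list[str]:
    """Every decamer a candidate primer's 3' terminus could occupy.

    Forward primers read the sense strand; reverse primers read the
    antisense strand, so their anchors are reverse-complemented windows.
    """
    L = len(chimera)
    anchors = []
    for n in range(cfg.end_len_min, cfg.end_len_max + 1):
        anchors.append(chimera[n - ANCHOR_LEN: n])                      # gene_5 3' end
        anchors.append(reverse_complement(chimera[L - n: L - n + ANCHOR_LEN]))  # gene_3
    for off in range(cfg.offset_min, cfg.offset_max + 1):
        p2 = cfg.fwd_frag2_base + off
        q1 = cfg.rev_frag1_base + off
        anchors.append(chimera[junction + p2 - ANCHOR_LEN: junction + p2])  # overlap_5
        anchors.append(reverse_complement(
            chimera[junction - q1: junction - q1 + ANCHOR_LEN]))            # overlap_3
    return anchors


def _priming_is_unique(chimera: str, junction: int, cfg: DesignConfig) -> bool:
    rc = reverse_complement(chimera)

    def count(needle: str) -> int:
        total, pos = 0, chimera.find(needle)
        while pos != -1:
            total += 1
            pos = chimera.find(needle, pos + 1)
        pos = rc.find(needle)
        while pos != -1:
            total += 1
            pos = rc.find(needle, pos + 1)
        return total

    return all(count(a) == 1 for a in _anchor_windows(chimera, junction, cfg))


def generate_pair(spec: FixtureSpec, cfg: DesignConfig = DEFAULT_CONFIG,
                  max_tries: int = 500) -> FragmentPair:
    """Deterministic fragment pair for ``spec.seed``.

    Candidates failing the unique-priming screen (when enabled) are
    resampled from the same seeded stream, so the result is still a pure
    function of the spec.
    """
    rng = random.Random(spec.seed)
    for _ in range(max_tries):
        frag1 = _random_fragment(rng, spec.len1, spec.gc_target)
        frag2 = _random_fragment(rng, spec.len2, spec.gc_target)
        if spec.junction_motif:
            motif = spec.junction_motif
            half = len(motif) // 2
            left = motif[:half] if half <= spec.len1 else motif[:spec.len1]
            right = motif[len(left):]
            frag1 = frag1[: spec.len1 - len(left)] + left
            frag2 = right + frag2[len(right):]
        chimera = frag1 + frag2
        if spec.unique_priming and not _priming_is_unique(chimera, spec.len1, cfg):
            continue
        return FragmentPair(
            first=FragmentRecord(name=f"synth1_seed{spec.seed}", sequence=frag1),
            second=FragmentRecord(name=f"synth2_seed{spec.seed}", sequence=frag2),
        )
    raise ConfigError(
        f"could not generate a unique-priming pair in {max_tries} tries "
        f"(spec={spec}); relax the spec or disable unique_priming"
    )


def write_demo_fasta(pair: FragmentPair, directory: str | Path) -> tuple[Path, Path]:
    """Write the pair as two single-record FASTA files usable by the CLI."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p1 = write_fragment(pair.first, directory / f"{pair.first.name}.fasta")
    p2 = write_fragment(pair.second, directory / f"{pair.second.name}.fasta")
    return p1, p2
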