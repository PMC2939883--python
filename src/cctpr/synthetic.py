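"""Synthetic proteomes with known ground truth for pipeline validation.

Three protein categories are generated:

* **background** — i.i.d. residues from a background distribution; contains no
  TPR domain.
* **planted** — one three-motif TPR domain (motifs sampled per-column from the
  motif profiles, clamp residues forced to consensus) embedded at a random
  interior offset, with linkers sampled from the configured range.
* **decoy** — like planted, but a chosen number of the five clamp positions is
  broken with a residue from a different substitution class. Breaks are made
  register-robust: the two residues flanking a broken position are also forced
  outside the consensus residue's class, so a +/-1 register rescue can never
  restore a broken position and decoys test the clamp rule itself.

Generation is a pure function of the spec (seed included).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .clamp import SUBSTITUTION_CLASSES, _class_of
from .errors import SyntheticSpecError
from .profiles import (
    AA_INDEX,
    CLAMP_CONSENSUS,
    MOTIF_LENGTH,
    PositionProfile,
)
from .seqio import AMINO_ACIDS, MOTIF_INDICES, ProteinRecord

_AA = np.array(list(AMINO_ACIDS))

#: The five clamp sites as (motif_index, position) pairs, in motif order.
CLAMP_SITES: tuple[tuple[str, int], ...] = tuple(
    (mi, q) for mi in MOTIF_INDICES for q in sorted(CLAMP_CONSENSUS[mi])
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic proteome."""

    n_background: int = 50
    n_planted: int = 50
    n_decoys: int = 50
    protein_length: tuple[int, int] = (200, 800)
    linker_length: tuple[int, int] = (0, 60)
    decoy_radical_positions: int = 3
    residue_background: tuple[float, ...] = tuple([1.0 / 20.0] * 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_planted, self.n_decoys) < 0:
            raise SyntheticSpecError("counts must be >= 0")
        lo, hi = self.protein_length
        llo, lhi = self.linker_length
        if not (0 <= llo <= lhi <= 60):
            raise SyntheticSpecError("linker_length must lie within [0, 60]")
        max_domain = 3 * MOTIF_LENGTH + 2 * lhi
        if lo > hi or hi < max_domain + 2:
            raise SyntheticSpecError(
                f"protein_length {self.protein_length} cannot host a "
                f"three-motif domain of up to {max_domain} residues"
            )
        if not 3 <= self.decoy_radical_positions <= 5:
            raise SyntheticSpecError("decoy_radical_positions must be in [3, 5]")
        p = np.asarray(self.residue_background)
        if p.shape != (20,) or not np.isclose(p.sum(), 1.0):
            raise SyntheticSpecError("residue_background must be 20 "
                                     "probabilities summing to 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated protein."""

    protein_id: str
    category: str  # background | planted | decoy
    motif_starts: tuple[int, int, int] | None = None
    broken_sites: tuple[tuple[str, int], ...] = ()


def _draw_outside_class(
    column_probs: np.ndarray, consensus: str, rng: np.random.Generator
) -> str:
    """Sample a residue from a profile column, excluding the consensus
    residue's substitution class."""
    cls = _class_of(consensus, SUBSTITUTION_CLASSES)
    mask = np.array([a not in cls for a in AMINO_ACIDS], dtype=float)
    p = column_probs * mask
    p /= p.sum()
    return str(rng.choice(_AA, p=p))


def sample_motif(
    profile: PositionProfile,
    rng: np.random.Generator,
    force_clamp: bool = False,
    break_positions: Sequence[int] = (),
) -> str:
    """Draw one 34-mer from a motif profile's per-column distributions.

    With ``force_clamp`` the motif's clamp positions are overwritten with
    their consensus residues. ``break_positions`` (clamp positions of this
    motif) are instead overwritten with an out-of-class residue, and their
    immediate neighbors are forced out of the consensus class as well so a
    one-residue register shift cannot restore the break.
    """
    residues = [
        str(rng.choice(_AA, p=profile.probabilities[c]))
        for c in range(MOTIF_LENGTH)
    ]
    sites = CLAMP_CONSENSUS[profile.motif_index]
    if force_clamp:
        for q, consensus in sites.items():
            residues[q - 1] = consensus
    for q in break_positions:
        consensus = sites[q]
        cls = _class_of(consensus, SUBSTITUTION_CLASSES)
        residues[q - 1] = _draw_outside_class(profile.probabilities[q - 1],
                                              consensus, rng)
        for flank in (q - 1, q + 1):
            j = flank - 1
            if 0 <= j < MOTIF_LENGTH and flank not in sites \
                    and residues[j] in cls:
                residues[j] = _draw_outside_class(profile.probabilities[j],
                                                  consensus, rng)
    return "".join(residues)


def _background_seq(length: int, probs: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    return rng.choice(_AA, size=length, p=probs)


def _embed_domain(
    spec: SyntheticSpec,
    profiles: Mapping[str, PositionProfile],
    rng: np.random.Generator,
    broken: Sequence[tuple[str, int]],
) -> tuple[str, tuple[int, int, int]]:
    llo, lhi = spec.linker_length
    linker1 = int(rng.integers(llo, lhi + 1))
    linker2 = int(rng.integers(llo, lhi + 1))
    motifs = []
    for mi in MOTIF_INDICES:
        breaks = [q for (bmi, q) in broken if bmi == mi]
        motifs.append(
            sample_motif(profiles[mi], rng, force_clamp=True,
                         break_positions=breaks)
        )
    domain = (motifs[0] + "X" * linker1 + motifs[1] + "X" * linker2
              + motifs[2])  # X marks splice slots, replaced below
    dlen = len(domain)
    lo, hi = spec.protein_length
    length = int(rng.integers(max(lo, dlen + 2), hi + 1))
    seq = _background_seq(length, np.asarray(spec.residue_background), rng)
    # interior offset: at least one background residue on each side
    start0 = int(rng.integers(1, length - dlen))
    arr = list(domain)
    # fill linker slots with background draws
    for k, ch in enumerate(arr):
        if ch == "X":
            arr[k] = str(rng.choice(_AA,
                                    p=np.asarray(spec.residue_background)))
    seq[start0:start0 + dlen] = arr
    s1 = start0 + 1  # 1-based
    s2 = s1 + MOTIF_LENGTH + linker1
    s3 = s2 + MOTIF_LENGTH + linker2
    return "".join(seq), (s1, s2, s3)


def generate_proteome(
    spec: SyntheticSpec,
    profiles: Mapping[str, PositionProfile],
) -> tuple[list[ProteinRecord], list[TruthRecord]]:
    """Generate a synthetic proteome and its ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    bg_probs = np.asarray(spec.residue_background)
    records: list[ProteinRecord] = []
    truths: list[TruthRecord] = []
    for k in range(spec.n_background):
        length = int(rng.integers(spec.protein_length[0],
                                  spec.protein_length[1] + 1))
        seq = "".join(_background_seq(length, bg_probs, rng))
        pid = f"bg{k:04d}"
        records.append(ProteinRecord(id=pid, sequence=seq,
                                     description="background"))
        truths.append(TruthRecord(protein_id=pid, category="background"))
    for k in range(spec.n_planted):
        seq, starts = _embed_domain(spec, profiles, rng, broken=())
        pid = f"planted{k:04d}"
        records.append(ProteinRecord(id=pid, sequence=seq,
                                     description="planted CC-TPR domain"))
        truths.append(TruthRecord(protein_id=pid, category="planted",
                                  motif_starts=starts))
    for k in range(spec.n_decoys):
        picks = rng.choice(len(CLAMP_SITES),
                           size=spec.decoy_radical_positions, replace=False)
        broken = tuple(CLAMP_SITES[i] for i in sorted(picks))
        seq, starts = _embed_domain(spec, profiles, rng, broken=broken)
        pid = f"decoy{k:04d}"
        records.append(ProteinRecord(id=pid, sequence=seq,
                                     description="clamp-broken decoy domain"))
        truths.append(TruthRecord(protein_id=pid, category="decoy",
                                  motif_starts=starts, broken_sites=broken))
    return records, truths


def write_truth_tsv(truths: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcategory\tstart_I\tstart_II\tstart_III\t"
                 "broken_sites\n")
        for t in truths:
            starts = t.motif_starts or ("", "", "")
            broken = ",".join(f"{mi}{q}" for mi, q in t.broken_sites)
            fh.write(f"{t.protein_id}\t{t.category}\t{starts[0]}\t{starts[1]}"
                     f"\t{starts[2]}\t{broken}\n")
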