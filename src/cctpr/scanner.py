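"""Sliding-window motif detection and three-motif TPR domain assembly.

A clamp-type TPR domain is an ordered triplet of 34-residue motifs (I, II, III)
separated by short linkers. The scanner scores every 34-mer of a protein
against all three motif profiles, reports windows meeting the per-motif
threshold, collapses same-index hits that crowd one repeat, and chains hits
into domains whose linkers fall in the configured range. A one-residue
register rescue relocates a motif start by +/-1 when that strictly improves
the carboxylate-clamp match (the documented case being a motif printed one
residue downstream of its true start).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import clamp as clamp_mod
from .errors import FixtureIntegrityError
from .profiles import (
    AA_INDEX,
    CLAMP_CONSENSUS,
    MOTIF_LENGTH,
    PositionProfile,
    default_thresholds,
)
from .seqio import MOTIF_INDICES, MotifFixtureRow, ProteinRecord

#: Default linker range (residues between consecutive motifs), derived from
#: the printed spacings of the reference alignment: 0 to 56, with one
#: documented one-residue overlap.
DEFAULT_LINKER_RANGE: tuple[int, int] = (-2, 60)

#: Same-index hits whose starts lie within this many residues are collapsed
#: to the local score maximum (prevents double-reporting of one repeat).
COLLAPSE_WINDOW = 17


@dataclass(frozen=True)
class TprMotif:
    """One detected (or fixture-derived) 34-residue TPR motif."""

    motif_index: str
    start: int  # 1-based inclusive
    window: str
    score: float
    register_shift: int = 0

    @property
    def end(self) -> int:
        return self.start + len(self.window) - 1


@dataclass(frozen=True)
class TprDomain:
    """An ordered (I, II, III) motif triplet."""

    motifs: tuple[TprMotif, TprMotif, TprMotif]

    def __post_init__(self) -> None:
        indices = tuple(m.motif_index for m in self.motifs)
        if indices != MOTIF_INDICES:
            raise FixtureIntegrityError(f"domain motifs out of order: {indices}")

    @property
    def linkers(self) -> tuple[int, int]:
        a, b, c = self.motifs
        return (b.start - a.end - 1, c.start - b.end - 1)

    @property
    def start(self) -> int:
        return self.motifs[0].start

    @property
    def end(self) -> int:
        return self.motifs[2].end

    @property
    def total_score(self) -> float:
        return sum(m.score for m in self.motifs)


def _encode(sequence: str) -> np.ndarray:
    """Map residues to profile column indices; X gets the zero-score slot 20."""
    return np.array([AA_INDEX.get(ch, 20) for ch in sequence], dtype=np.intp)


def scan_protein(
    protein: ProteinRecord,
    profiles: Mapping[str, PositionProfile],
    thresholds: Mapping[str, float] | None = None,
    collapse_window: int = COLLAPSE_WINDOW,
) -> list[TprMotif]:
    """Score every 34-mer window against all three profiles.

    Returns motifs sorted by start position. Windows shorter than 34 residues
    yield an empty list. Overlapping hits of the same motif index (starts
    within ``collapse_window`` residues) are resolved to the score maximum,
    ties to the smallest start.
    """
    if thresholds is None:
        thresholds = default_thresholds(profiles)
    if len(protein) < MOTIF_LENGTH:
        return []
    idx = _encode(protein.sequence)
    windows = np.lib.stride_tricks.sliding_window_view(idx, MOTIF_LENGTH)
    cols = np.arange(MOTIF_LENGTH)
    hits: list[TprMotif] = []
    for mi, profile in profiles.items():
        lo = np.hstack([profile.log_odds, np.zeros((MOTIF_LENGTH, 1))])
        scores = lo[cols[None, :], windows].sum(axis=1)
        for i in np.flatnonzero(scores >= thresholds[mi]):
            start = int(i) + 1
            hits.append(
                TprMotif(
                    motif_index=mi,
                    start=start,
                    window=protein.sequence[i:i + MOTIF_LENGTH],
                    score=float(scores[i]),
                )
            )
    collapsed: list[TprMotif] = []
    for mi in MOTIF_INDICES:
        same = sorted((h for h in hits if h.motif_index == mi),
                      key=lambda h: h.start)
        cluster: list[TprMotif] = []
        for hit in same:
            if cluster and hit.start - cluster[-1].start < collapse_window:
                cluster.append(hit)
            else:
                if cluster:
                    collapsed.append(max(cluster,
                                         key=lambda h: (h.score, -h.start)))
                cluster = [hit]
        if cluster:
            collapsed.append(max(cluster, key=lambda h: (h.score, -h.start)))
    return sorted(collapsed, key=lambda h: (h.start, h.motif_index))


def assemble_domains(
    motifs: Sequence[TprMotif],
    linker_range: tuple[int, int] = DEFAULT_LINKER_RANGE,
) -> list[TprDomain]:
    """Chain I -> II -> III motif hits into three-motif domains.

    Every chain whose two linkers fall inside ``linker_range`` is a candidate;
    a maximal set of non-overlapping candidates is then chosen greedily by
    summed profile score (ties to the smallest start). A protein may yield
    more than one domain.
    """
    lo, hi = linker_range
    by_index = {mi: [m for m in motifs if m.motif_index == mi]
                for mi in MOTIF_INDICES}
    candidates: list[TprDomain] = []
    for m1 in by_index["I"]:
        for m2 in by_index["II"]:
            if not lo <= m2.start - m1.end - 1 <= hi:
                continue
            for m3 in by_index["III"]:
                if lo <= m3.start - m2.end - 1 <= hi:
                    candidates.append(TprDomain(motifs=(m1, m2, m3)))
    candidates.sort(key=lambda d: (-d.total_score, d.start))
    chosen: list[TprDomain] = []
    for cand in candidates:
        if all(cand.end < d.start or cand.start > d.end for d in chosen):
            chosen.append(cand)
    return sorted(chosen, key=lambda d: d.start)


def _residue_at(motif: TprMotif, protein: ProteinRecord | None,
                position: int, shift: int) -> str | None:
    """Residue at 1-based motif ``position`` under a candidate register shift.

    With the full protein available the residue is read from the sequence;
    otherwise it is read from the printed window, where a shifted position may
    fall outside the excised region (returns None: unknown).
    """
    if protein is not None:
        i = motif.start + shift + position - 2  # 0-based in protein
        if 0 <= i < len(protein.sequence):
            return protein.sequence[i]
        return None
    j = position - 1 + shift  # 0-based in printed window
    if 0 <= j < len(motif.window):
        return motif.window[j]
    return None


def register_rescue(
    domain: TprDomain,
    protein: ProteinRecord | None = None,
    clamp: Mapping[str, Mapping[int, str]] = CLAMP_CONSENSUS,
    classes: Sequence[frozenset[str]] | None = None,
) -> TprDomain:
    """Apply a +/-1 register shift to any motif where it strictly improves
    the clamp match.

    A shift is applied only when it strictly increases the number of clamp
    positions holding an acceptable residue (the consensus residue or a
    same-class conservative replacement); ties keep the printed register.
    Counting acceptable rather than only exact matches keeps conservatively
    substituted motifs (e.g. K2->R) at their printed register instead of
    chasing a chance exact match one residue away.
    """
    new_motifs = []
    for motif in domain.motifs:
        sites = clamp[motif.motif_index]

        def acceptable(shift: int) -> int:
            n = 0
            for q, expected in sites.items():
                obs = _residue_at(motif, protein, q, shift)
                if obs is None or obs == "X":
                    continue
                status = clamp_mod.substitution_status(expected, obs, classes)
                if status in ("consensus", "conservative"):
                    n += 1
            return n

        best_shift, best_n = 0, acceptable(0)
        for shift in (-1, +1):
            if motif.start + shift < 1:
                continue
            if protein is not None and motif.start + shift + MOTIF_LENGTH - 1 \
                    > len(protein.sequence):
                continue
            n = acceptable(shift)
            if n > best_n:
                best_shift, best_n = shift, n
        if best_shift == 0:
            new_motifs.append(motif)
            continue
        new_start = motif.start + best_shift
        if protein is not None:
            window = protein.sequence[new_start - 1:new_start - 1 + MOTIF_LENGTH]
        elif best_shift == -1:
            window = "X" + motif.window[:MOTIF_LENGTH - 1]
        else:
            window = motif.window[1:] + "X"
        new_motifs.append(
            replace(motif, start=new_start, window=window,
                    register_shift=best_shift)
        )
    return TprDomain(motifs=tuple(new_motifs))


def domain_from_fixture_rows(
    triplet: Sequence[MotifFixtureRow],
    profiles: Mapping[str, PositionProfile] | None = None,
) -> TprDomain:
    """Build a domain from an ordered fixture triplet (I, II, III).

    Scores come from the supplied profiles when the printed motif is
    full-length; length-anomalous rows score 0.
    """
    motifs = []
    for row in triplet:
        score = 0.0
        if profiles is not None and not row.length_anomaly:
            score = profiles[row.motif_index].score_window(row.motif_seq)
        motifs.append(
            TprMotif(
                motif_index=row.motif_index,
                start=row.start,
                window=row.motif_seq,
                score=score,
            )
        )
    return TprDomain(motifs=tuple(motifs))
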