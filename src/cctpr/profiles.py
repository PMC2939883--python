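"""Position-specific scoring profiles for the three 34-residue TPR motifs.

A tetratricopeptide repeat (TPR) is a degenerate 34-amino-acid helix-turn-helix
motif. Clamp-type (carboxylate clamp, CC) three-motif TPR domains bind the
acidic C-terminal EEVD peptides of cytosolic Hsp90/Hsp70 through five basic or
polar residues: K5 and N9 in motif I, N6 in motif II, K2 and R6 in motif III.

Each motif (I, II, III) gets its own 34-column log-odds profile, trained from
the packaged motif alignments. Column probabilities use Laplace-style
pseudocounts so every score is finite:

    p_c(a) = (count(a, c) + kappa) / (N + 20 * kappa)
    score_c(a) = log2(p_c(a) / background(a))

and a window's score is the sum of its per-column log-odds (``X`` contributes
zero). ``training_min_score`` — the lowest self-score of any full-length
training motif — anchors the default scan threshold: a window is reported when
it scores at least ``training_min_score - margin`` (default margin 2 bits),
which admits every training motif plus near relatives while rejecting random
windows by a wide gap.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, WindowLengthError
from .seqio import AMINO_ACIDS, MotifFixtureRow

MOTIF_LENGTH = 34

#: residue -> column index into the 20-wide profile tables
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Structure-maintaining consensus: eight positions with elevated conservation
#: that stabilize the two helices of each motif.
STRUCTURAL_CONSENSUS: dict[int, frozenset[str]] = {
    4: frozenset("WLF"),
    7: frozenset("LIM"),
    8: frozenset("GAS"),
    11: frozenset("YLF"),
    20: frozenset("ASE"),
    24: frozenset("FYL"),
    27: frozenset("ASL"),
    32: frozenset("PKE"),
}

#: Carboxylate-clamp consensus per motif (1-based positions within the motif):
#: K5/N9 - N6 - K2/R6.
CLAMP_CONSENSUS: dict[str, dict[int, str]] = {
    "I": {5: "K", 9: "N"},
    "II": {6: "N"},
    "III": {2: "K", 6: "R"},
}

#: Default margin (bits) below the weakest training motif for scan thresholds.
DEFAULT_THRESHOLD_MARGIN = 2.0


def uniform_background() -> np.ndarray:
    """Uniform residue background (1/20); the package default."""
    return np.full(20, 1.0 / 20.0)


@dataclass(frozen=True)
class PositionProfile:
    """34-column log-odds scoring model for one TPR motif.

    Attributes
    ----------
    motif_index:
        "I", "II" or "III".
    probabilities:
        (34, 20) per-column residue probabilities after pseudocounting; each
        row sums to 1. Also the sampling distribution used by the synthetic
        proteome generator.
    log_odds:
        (34, 20) log2(probability / background) scores.
    training_min_score:
        Minimum self-score over the full-length training motifs.
    """

    motif_index: str
    probabilities: np.ndarray
    log_odds: np.ndarray
    pseudocount: float
    background: np.ndarray
    training_min_score: float
    n_training: int

    def __post_init__(self) -> None:
        assert self.probabilities.shape == (MOTIF_LENGTH, 20)
        np.testing.assert_allclose(self.probabilities.sum(axis=1), 1.0,
                                   atol=1e-9)

    @property
    def length(self) -> int:
        return MOTIF_LENGTH

    def score_window(self, window: str) -> float:
        """Score one 34-residue window (sum of per-column log-odds; X -> 0)."""
        if len(window) != MOTIF_LENGTH:
            raise WindowLengthError(
                f"window length {len(window)} != {MOTIF_LENGTH}"
            )
        total = 0.0
        for c, ch in enumerate(window):
            if ch != "X":
                total += self.log_odds[c, AA_INDEX[ch]]
        return float(total)

    # ---- JSON round trip so scans are reproducible bit-exactly ----

    def to_json(self) -> str:
        return json.dumps(
            {
                "motif_index": self.motif_index,
                "probabilities": self.probabilities.tolist(),
                "log_odds": self.log_odds.tolist(),
                "pseudocount": self.pseudocount,
                "background": self.background.tolist(),
                "training_min_score": self.training_min_score,
                "n_training": self.n_training,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PositionProfile":
        d = json.loads(text)
        return cls(
            motif_index=d["motif_index"],
            probabilities=np.asarray(d["probabilities"]),
            log_odds=np.asarray(d["log_odds"]),
            pseudocount=d["pseudocount"],
            background=np.asarray(d["background"]),
            training_min_score=d["training_min_score"],
            n_training=d["n_training"],
        )


def build_profile(
    rows: Iterable[MotifFixtureRow | str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> PositionProfile:
    """Build a position profile for one motif from training rows.

    Rows whose printed motif is not 34 residues (length anomalies) are excluded
    from counting. ``rows`` may also be plain 34-mer strings (then the motif
    index must be inferable from fixture rows, so at least one fixture row is
    required for string-only input; for testing, strings plus an explicit
    first fixture row are accepted).
    """
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)
    seqs: list[str] = []
    motif_index = None
    for row in rows:
        if isinstance(row, MotifFixtureRow):
            if motif_index is None:
                motif_index = row.motif_index
            elif row.motif_index != motif_index:
                raise InsufficientDataError(
                    "training rows mix motif indices "
                    f"({motif_index} vs {row.motif_index})"
                )
            if not row.length_anomaly:
                seqs.append(row.motif_seq)
        else:
            seqs.append(str(row))
    if motif_index is None:
        motif_index = "I"
    if not seqs:
        raise InsufficientDataError("no full-length training motifs")
    counts = np.zeros((MOTIF_LENGTH, 20))
    for seq in seqs:
        if len(seq) != MOTIF_LENGTH:
            raise WindowLengthError(
                f"training motif length {len(seq)} != {MOTIF_LENGTH}"
            )
        for c, ch in enumerate(seq):
            counts[c, AA_INDEX[ch]] += 1
    n = len(seqs)
    probs = (counts + pseudocount) / (n + 20.0 * pseudocount)
    log_odds = np.log2(probs / background[None, :])
    profile = PositionProfile(
        motif_index=motif_index,
        probabilities=probs,
        log_odds=log_odds,
        pseudocount=float(pseudocount),
        background=background,
        training_min_score=0.0,
        n_training=n,
    )
    min_score = min(profile.score_window(s) for s in seqs)
    object.__setattr__(profile, "training_min_score", float(min_score))
    return profile


def build_motif_profiles(
    rows: Iterable[MotifFixtureRow],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> dict[str, PositionProfile]:
    """Build the three motif profiles from a mixed fixture row list."""
    by_index: dict[str, list[MotifFixtureRow]] = {"I": [], "II": [], "III": []}
    for row in rows:
        by_index[row.motif_index].append(row)
    return {
        mi: build_profile(mrows, pseudocount=pseudocount, background=background)
        for mi, mrows in by_index.items()
    }


def default_profiles(
    pseudocount: float = 1.0, background: np.ndarray | None = None
) -> dict[str, PositionProfile]:
    """Profiles trained on the pooled packaged alignments.

    The Arabidopsis rows (with the human Hop TPR2a reference, which the source
    alignment itself included) and the rice rows are pooled by default; the two
    length-anomalous rows are excluded from counting.
    """
    from .seqio import load_arabidopsis_motifs, load_rice_motifs

    rows = load_arabidopsis_motifs() + load_rice_motifs()
    return build_motif_profiles(rows, pseudocount=pseudocount,
                                background=background)


def default_thresholds(
    profiles: Mapping[str, PositionProfile],
    margin: float = DEFAULT_THRESHOLD_MARGIN,
) -> dict[str, float]:
    """Per-motif scan thresholds: training_min_score - margin (bits)."""
    return {mi: p.training_min_score - margin for mi, p in profiles.items()}
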