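"""Carboxylate-clamp evaluation, substitution typing and the CC-TPR verdict.

The clamp rule: a three-motif TPR domain is competent to bind the EEVD tails
of Hsp90/Hsp70 when the five clamp positions (K5, N9 | N6 | K2, R6) retain
their consensus residue or a conservative (same-class) replacement. A protein
is called CC-TPR positive when its best domain keeps at least ``min_matches``
of the five positions acceptable; the default of 3 is the smallest value that
accepts the weakest protein retained by the source screen (three exact
matches, two radical substitutions).

Substitution classes partition the 20 residues by side-chain volume and
polarity. The partition used here is chosen so that every replacement the
source screen treats as conservative (K<->R, N->Q) is within-class and every
replacement it treats as radical (K->E, R->A, R->M, N->S, N->D) is
across-class:

    {K,R,H}  {D,E}  {N,Q}  {S,T}  {F,Y,W}  {L,I,V,M}  {A,G}  {C}  {P}
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import FixtureIntegrityError
from .profiles import CLAMP_CONSENSUS
from .seqio import MOTIF_INDICES, ProteinMeta

#: Partition of the 20 standard residues by volume and polarity.
SUBSTITUTION_CLASSES: tuple[frozenset[str], ...] = (
    frozenset("KRH"),   # basic
    frozenset("DE"),    # acidic
    frozenset("NQ"),    # amide
    frozenset("ST"),    # small hydroxyl
    frozenset("FYW"),   # aromatic
    frozenset("LIVM"),  # aliphatic
    frozenset("AG"),    # tiny
    frozenset("C"),
    frozenset("P"),
)

ARCHITECTURE_CLASSES = (
    "single_TPR",
    "single_TPR_plus_domain",
    "multi_TPR",
    "multi_TPR_plus_domain",
)

DEFAULT_MIN_MATCHES = 3


def _class_of(residue: str,
              classes: Sequence[frozenset[str]]) -> frozenset[str] | None:
    for cls in classes:
        if residue in cls:
            return cls
    return None


def substitution_status(
    expected: str,
    observed: str,
    classes: Sequence[frozenset[str]] | None = None,
) -> str:
    """Type one clamp-position replacement.

    Returns "consensus" (identical), "conservative" (same substitution class)
    or "radical" (different class, or unknown residue X).
    """
    if classes is None:
        classes = SUBSTITUTION_CLASSES
    if observed == expected:
        return "consensus"
    cls = _class_of(expected, classes)
    if cls is not None and observed in cls:
        return "conservative"
    return "radical"


@dataclass(frozen=True)
class ClampSite:
    """Status of one clamp position in one motif."""

    motif_index: str
    position: int  # 1-based within the motif
    expected: str
    observed: str | None
    status: str


@dataclass(frozen=True)
class ClampEvaluation:
    """The five clamp-position statuses of one domain."""

    sites: tuple[ClampSite, ...]
    anomaly: bool = False

    def __post_init__(self) -> None:
        assert len(self.sites) == 5

    @property
    def n_match(self) -> int:
        """Clamp positions with consensus or conservative status."""
        return sum(s.status in ("consensus", "conservative")
                   for s in self.sites)

    @property
    def statuses(self) -> tuple[str, ...]:
        return tuple(s.status for s in self.sites)


def evaluate_clamp(
    domain,
    clamp: Mapping[str, Mapping[int, str]] = CLAMP_CONSENSUS,
    classes: Sequence[frozenset[str]] | None = None,
) -> ClampEvaluation:
    """Read and type the five clamp residues of a three-motif domain.

    Positions falling beyond a (length-anomalous) motif window are typed
    radical and flag the evaluation as anomalous.
    """
    sites: list[ClampSite] = []
    anomaly = False
    for motif in domain.motifs:
        for position in sorted(clamp[motif.motif_index]):
            expected = clamp[motif.motif_index][position]
            if position <= len(motif.window):
                observed = motif.window[position - 1]
                status = substitution_status(expected, observed, classes)
            else:
                observed, status, anomaly = None, "radical", True
            sites.append(
                ClampSite(
                    motif_index=motif.motif_index,
                    position=position,
                    expected=expected,
                    observed=observed,
                    status=status,
                )
            )
    return ClampEvaluation(sites=tuple(sites), anomaly=anomaly)


@dataclass(frozen=True)
class CCVerdict:
    """Protein-level CC-TPR decision."""

    protein_id: str
    is_cc_tpr: bool
    best_domain: object | None
    evaluation: ClampEvaluation | None
    n_match: int
    n_domains: int
    architecture_class: str | None = None


def classify_protein(
    protein_id: str,
    domains: Sequence,
    clamp: Mapping[str, Mapping[int, str]] = CLAMP_CONSENSUS,
    classes: Sequence[frozenset[str]] | None = None,
    min_matches: int = DEFAULT_MIN_MATCHES,
) -> CCVerdict:
    """Issue the CC-TPR verdict for one protein.

    Each assembled domain is clamp-evaluated; the best domain maximizes
    (n_match, total profile score), ties broken by smallest start. With no
    domains the verdict is negative.
    """
    if not domains:
        return CCVerdict(protein_id, False, None, None, 0, 0)
    scored = [(evaluate_clamp(d, clamp, classes), d) for d in domains]
    best_eval, best_domain = max(
        scored, key=lambda ed: (ed[0].n_match, ed[1].total_score, -ed[1].start)
    )
    return CCVerdict(
        protein_id=protein_id,
        is_cc_tpr=best_eval.n_match >= min_matches,
        best_domain=best_domain,
        evaluation=best_eval,
        n_match=best_eval.n_match,
        n_domains=len(domains),
    )


def architecture_class(multi_tpr: bool, has_extra_domain: bool) -> str:
    if multi_tpr:
        return "multi_TPR_plus_domain" if has_extra_domain else "multi_TPR"
    return "single_TPR_plus_domain" if has_extra_domain else "single_TPR"


def architecture_census(
    verdicts: Iterable[CCVerdict],
    meta: Iterable[ProteinMeta],
    annotations: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, dict[str, int]]:
    """Count CC-TPR-positive proteins per architecture class.

    Verdicts are joined to metadata on protein name or locus id. The number of
    TPR domains comes from the metadata when present (the screen's alignment
    fixtures carry only the best domain), otherwise from the verdict's domain
    count; extra functional domains come from the metadata and/or an external
    annotation table (protein -> domain names). Unmatched proteins are warned
    about and excluded.

    Returns counts keyed "novel", "known" and "all", each a dict over the four
    architecture classes.
    """
    # join on name or locus id; names are hyphen-insensitive because the
    # source tables typeset e.g. "AtToc64-III" and "AtToc64III" inconsistently
    by_key: dict[str, ProteinMeta] = {}
    for m in meta:
        by_key[m.name] = m
        by_key[m.name.replace("-", "")] = m
        by_key[m.locus_id] = m
    counts = {
        "novel": Counter(),
        "known": Counter(),
        "all": Counter(),
    }
    for verdict in verdicts:
        if not verdict.is_cc_tpr:
            continue
        m = by_key.get(verdict.protein_id) \
            or by_key.get(verdict.protein_id.replace("-", ""))
        if m is None:
            warnings.warn(
                f"no metadata for protein {verdict.protein_id!r}; "
                "excluded from census"
            )
            continue
        multi = m.n_tpr_domains == "more_than_one" or verdict.n_domains > 1
        extra = bool(m.additional_domains)
        if annotations is not None:
            extra = extra or bool(annotations.get(m.name)
                                  or annotations.get(m.locus_id))
        cls = architecture_class(multi, extra)
        counts["all"][cls] += 1
        counts["novel" if m.novel else "known"][cls] += 1
    return {
        subset: {cls: counter.get(cls, 0) for cls in ARCHITECTURE_CLASSES}
        for subset, counter in counts.items()
    }
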