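"""End-to-end pipelines: fixture classification and proteome screening."""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clamp import CCVerdict, DEFAULT_MIN_MATCHES, classify_protein
from .profiles import PositionProfile, default_profiles, default_thresholds
from .scanner import (
    DEFAULT_LINKER_RANGE,
    TprDomain,
    assemble_domains,
    domain_from_fixture_rows,
    register_rescue,
    scan_protein,
)
from .seqio import MotifFixtureRow, ProteinRecord, group_by_protein


def fixture_domains(
    rows: Iterable[MotifFixtureRow],
    profiles: Mapping[str, PositionProfile] | None = None,
    rescue: bool = True,
    include_reference: bool = True,
) -> dict[str, TprDomain]:
    """Build one (optionally register-rescued) domain per fixture protein."""
    grouped = group_by_protein(rows)
    out: dict[str, TprDomain] = {}
    for name, triplet in grouped.items():
        if not include_reference and triplet[0].is_reference:
            continue
        domain = domain_from_fixture_rows(triplet, profiles)
        if rescue:
            domain = register_rescue(domain)
        out[name] = domain
    return out


def classify_fixture_proteins(
    rows: Iterable[MotifFixtureRow],
    profiles: Mapping[str, PositionProfile] | None = None,
    min_matches: int = DEFAULT_MIN_MATCHES,
    rescue: bool = True,
    include_reference: bool = False,
) -> list[CCVerdict]:
    """Classify every fixture protein from its excised motif triplet.

    The human Hop reference row is excluded by default so that positive counts
    refer to the screened proteomes.
    """
    domains = fixture_domains(rows, profiles, rescue=rescue,
                              include_reference=include_reference)
    return [
        classify_protein(name, [domain], min_matches=min_matches)
        for name, domain in domains.items()
    ]


def screen_proteome(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, PositionProfile] | None = None,
    thresholds: Mapping[str, float] | None = None,
    linker_range: tuple[int, int] = DEFAULT_LINKER_RANGE,
    min_matches: int = DEFAULT_MIN_MATCHES,
    rescue: bool = True,
) -> list[CCVerdict]:
    """Scan, assemble, rescue and classify every protein of a proteome."""
    if profiles is None:
        profiles = default_profiles()
    if thresholds is None:
        thresholds = default_thresholds(profiles)
    verdicts = []
    for record in records:
        motifs = scan_protein(record, profiles, thresholds)
        domains = assemble_domains(motifs, linker_range)
        if rescue:
            domains = [register_rescue(d, protein=record) for d in domains]
        verdicts.append(classify_protein(record.id, domains,
                                         min_matches=min_matches))
    return verdicts


def motifs_to_frame(protein_id: str, motifs) -> pd.DataFrame:
    """Tabulate scan hits (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            {
                "protein_id": protein_id,
                "motif_index": m.motif_index,
                "start": m.start,
                "end": m.end,
                "score": m.score,
                "register_shift": m.register_shift,
            }
            for m in motifs
        ]
    )


def verdicts_to_frame(verdicts: Iterable[CCVerdict]) -> pd.DataFrame:
    """Tabulate verdicts with per-position clamp statuses."""
    rows = []
    for v in verdicts:
        row = {
            "protein_id": v.protein_id,
            "is_cc_tpr": v.is_cc_tpr,
            "n_match": v.n_match,
            "n_domains": v.n_domains,
            "architecture_class": v.architecture_class,
        }
        if v.evaluation is not None:
            for site in v.evaluation.sites:
                key = f"{site.motif_index}{site.position}"
                row[f"status_{key}"] = site.status
                row[f"observed_{key}"] = site.observed
        rows.append(row)
    return pd.DataFrame(rows)
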