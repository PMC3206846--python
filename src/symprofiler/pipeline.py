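"""End-to-end orchestration: sequences + peak tables in, community
comparisons and symbiont classifications out."""

from __future__ import annotations

from typing import Mapping, Sequence

from .classify import OTUAnnotation, classify_all
from .digest import build_reference_db
from .diversity import anosim, bray_curtis
from .io import PeakProfile, SampleMetadata, SequenceRecord
from .matching import ToleranceBins, build_signatures, match_trfs
from .otus import build_otu_table, cluster_otus
from .trflp import align_trfs, variable_threshold_standardize

__all__ = ["run_pipeline"]


def run_pipeline(
    records: Sequence[SequenceRecord],
    sample_of: Mapping[str, str],
    metadata: Sequence[SampleMetadata],
    profiles: Sequence[PeakProfile],
    annotations: Mapping[str, OTUAnnotation] | None = None,
    hosts: Sequence[str] | None = None,
    seawater_source: str = "seawater",
    identity_threshold: float = 0.99,
    enzymes: Sequence[str] = ("HaeIII", "MspI", "RsaI"),
    window: tuple[float, float] = (100.0, 500.0),
    tolerance_bins: ToleranceBins = ToleranceBins(),
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Run cluster -> digest -> standardize -> align -> match -> stats ->
    classify on one dataset; returns all intermediate products keyed by
    stage."""
    assignments = cluster_otus(records, threshold=identity_threshold)
    table = build_otu_table(assignments, records, metadata, sample_of=sample_of)
    db = build_reference_db(table.representative, enzymes=enzymes, window=window)

    matrices = {}
    chosen_pct = {}
    for enzyme in enzymes:
        enz_profiles = [p for p in profiles if p.enzyme == enzyme]
        if not enz_profiles:
            continue
        filtered, pct = variable_threshold_standardize(enz_profiles, window=window)
        matrices[enzyme] = align_trfs(filtered, mode="relative")
        chosen_pct[enzyme] = pct

    matches = match_trfs(db, matrices, bins=tolerance_bins)
    signatures, sig_summary = build_signatures(matches)

    groups = {m.sample_id: m.source for m in metadata}
    d_otu = bray_curtis(table.counts.T, transform="sqrt")
    anosim_otu = anosim(d_otu, groups, n_perm=n_perm, seed=seed)
    anosim_trf = {}
    for enzyme, mat in matrices.items():
        d_trf = bray_curtis(mat.abundance, transform="sqrt", relative=False)
        anosim_trf[enzyme] = anosim(
            d_trf, {s: groups[s] for s in mat.abundance.index},
            n_perm=n_perm, seed=seed,
        )
    anosim_trf_combined = None
    if matrices:
        # composite fingerprint: per-enzyme relative matrices side by side
        import pandas as pd

        combined = pd.concat(
            {e: m.abundance for e, m in matrices.items()}, axis=1
        ).fillna(0.0)
        d_comb = bray_curtis(combined, transform="sqrt")
        anosim_trf_combined = anosim(
            d_comb, {s: groups[s] for s in combined.index},
            n_perm=n_perm, seed=seed,
        )

    classification = None
    if annotations is not None:
        if hosts is None:
            hosts = sorted(
                {m.source for m in metadata} - {seawater_source}
            )
        # annotations are keyed by planted phylotype or by clone id; map to
        # cluster centroids through any member
        ann = {}
        for centroid, members in assignments.items():
            for mid in [centroid, *members]:
                if mid in annotations:
                    ann[centroid] = OTUAnnotation(
                        centroid, annotations[mid].closest_env_identity,
                        annotations[mid].taxon,
                    )
                    break
        classification = classify_all(
            table, ann, hosts, seawater_source=seawater_source
        )

    return {
        "assignments": assignments,
        "table": table,
        "db": db,
        "matrices": matrices,
        "threshold_pct": chosen_pct,
        "matches": matches,
        "signatures": signatures,
        "signature_summary": sig_summary,
        "anosim_otu": anosim_otu,
        "anosim_trf": anosim_trf,
        "anosim_trf_combined": anosim_trf_combined,
        "classification": classification,
    }
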