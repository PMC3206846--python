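"""Matching empirical T-RFs to predicted reference T-RFs.

Electrophoretic sizing drifts from the true fragment length, and the drift
grows with fragment size, so matches are accepted inside size-dependent
tolerance bins: +/-1.0 bp up to 200 bp, +/-1.5 bp for 201-400 bp, and
+/-4.0 bp above 400 bp by default. A phylotype's *T-RFLP signature* is the
set of (enzyme, matched bin) pairs it explains; signatures are classified
as unique (no other phylotype shares the identical set), shared, or
undetected (no in-window prediction matched anything).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .digest import ReferenceTRFDatabase
from .io import SequenceRecord
from .otus import pairwise_identity
from .trflp import AlignedTRFMatrix

__all__ = [
    "ToleranceBins",
    "TRFSignature",
    "tolerance_for",
    "match_trfs",
    "build_signatures",
    "shared_signature_divergence",
    "taxonomic_bias_gtest",
]

INF = float("inf")


@dataclass(frozen=True)
class ToleranceBins:
    """Ordered (upper size bound, tolerance) rules; bounds are inclusive."""

    rules: tuple[tuple[float, float], ...] = ((200.0, 1.0), (400.0, 1.5), (INF, 4.0))

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.rules]
        if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise ValueError("tolerance bounds must be strictly increasing")
        if any(t <= 0 for _, t in self.rules):
            raise ValueError("tolerances must be positive")


def tolerance_for(size: float, bins: ToleranceBins = ToleranceBins()) -> float:
    """Tolerance of the first rule whose bound covers ``size`` (inclusive)."""
    if size < 0:
        raise ValueError("size must be non-negative")
    for bound, tol in bins.rules:
        if size <= bound:
            return tol
    raise AssertionError("unreachable: last bound is infinite")


@dataclass
class TRFSignature:
    otu_id: str
    matched: dict[str, float | None]  # enzyme -> matched bin center or None
    resolution: str = "undetected"  # unique | shared | undetected

    @property
    def n_enzymes_matched(self) -> int:
        return sum(1 for v in self.matched.values() if v is not None)

    @property
    def key(self) -> tuple[tuple[str, float], ...]:
        """Canonical matched-set key used for signature equality."""
        return tuple(
            sorted((e, v) for e, v in self.matched.items() if v is not None)
        )


def match_trfs(
    db: ReferenceTRFDatabase,
    matrices: Mapping[str, AlignedTRFMatrix],
    bins: ToleranceBins = ToleranceBins(),
) -> dict[str, dict[str, float | None]]:
    """Match each phylotype's in-window predictions to empirical bins.

    Returns OTU -> enzyme -> matched bin center (or None). A prediction
    matches the nearest empirical bin within its tolerance; ties go to the
    smaller bin size.
    """
    unknown = set(matrices) - set(db.enzymes)
    if unknown:
        raise ValueError(f"matrices for enzymes absent from the database: {sorted(unknown)}")
    out: dict[str, dict[str, float | None]] = {}
    for otu, preds in db.entries.items():
        out[otu] = {}
        for enzyme in db.enzymes:
            pred = preds[enzyme]
            matched = None
            if enzyme in matrices and pred is not None and db.in_window(otu, enzyme):
                tol = tolerance_for(pred, bins)
                candidates = [
                    b
                    for b in matrices[enzyme].bins
                    if abs(pred - b) <= tol
                ]
                if candidates:
                    matched = min(candidates, key=lambda b: (abs(pred - b), b))
            out[otu][enzyme] = matched
    return out


def trfs_explained(
    matches: Mapping[str, Mapping[str, float | None]],
) -> dict[tuple[str, float], list[str]]:
    """Invert matches: (enzyme, bin) -> phylotypes it may represent."""
    inv: dict[tuple[str, float], list[str]] = {}
    for otu, per_enzyme in matches.items():
        for enzyme, b in per_enzyme.items():
            if b is not None:
                inv.setdefault((enzyme, b), []).append(otu)
    return {k: sorted(v) for k, v in inv.items()}


def build_signatures(
    matches: Mapping[str, Mapping[str, float | None]],
) -> tuple[list[TRFSignature], dict]:
    """Assign resolution classes and summarize signature sharing."""
    sigs = [
        TRFSignature(otu_id=otu, matched=dict(per_enzyme))
        for otu, per_enzyme in sorted(matches.items())
    ]
    by_key: dict[tuple, list[TRFSignature]] = {}
    for sig in sigs:
        if sig.n_enzymes_matched == 0:
            sig.resolution = "undetected"
        else:
            by_key.setdefault(sig.key, []).append(sig)
    for group in by_key.values():
        res = "unique" if len(group) == 1 else "shared"
        for sig in group:
            sig.resolution = res

    counts = {r: sum(1 for s in sigs if s.resolution == r)
              for r in ("unique", "shared", "undetected")}
    by_n: dict[int, dict[str, int]] = {}
    for sig in sigs:
        d = by_n.setdefault(sig.n_enzymes_matched, {"unique": 0, "shared": 0,
                                                    "undetected": 0})
        d[sig.resolution] += 1
    group_sizes = [len(g) for g in by_key.values() if len(g) > 1]
    summary = {
        "n_otus": len(sigs),
        "resolution_counts": counts,
        "by_n_enzymes_matched": by_n,
        "otus_per_shared_signature": {
            "mean": float(np.mean(group_sizes)) if group_sizes else None,
            "se": (
                float(np.std(group_sizes, ddof=1) / math.sqrt(len(group_sizes)))
                if len(group_sizes) > 1
                else None
            ),
        },
    }
    return sigs, summary


def shared_signature_divergence(
    signatures: Sequence[TRFSignature],
    sequences: Mapping[str, SequenceRecord],
) -> dict[int, dict[str, float | None]]:
    """Mean within-group sequence divergence (%) of shared signatures,
    stratified by the number of enzymes matched; SE over group means."""
    groups: dict[tuple, list[TRFSignature]] = {}
    for sig in signatures:
        if sig.resolution == "shared":
            groups.setdefault(sig.key, []).append(sig)
    strata: dict[int, list[float]] = {}
    for key, members in groups.items():
        divs = [
            (1.0 - pairwise_identity(sequences[a.otu_id], sequences[b.otu_id])) * 100.0
            for a, b in itertools.combinations(members, 2)
        ]
        strata.setdefault(members[0].n_enzymes_matched, []).append(
            float(np.mean(divs))
        )
    out: dict[int, dict[str, float | None]] = {}
    for n, means in sorted(strata.items()):
        out[n] = {
            "n_groups": len(means),
            "mean_divergence_pct": float(np.mean(means)),
            "se": (
                float(np.std(means, ddof=1) / math.sqrt(len(means)))
                if len(means) > 1
                else None
            ),
        }
    return out


def taxonomic_bias_gtest(
    matched_taxa_counts: Mapping[str, float],
    reference_taxa_counts: Mapping[str, float],
) -> tuple[float, int, float]:
    """Goodness-of-fit G test of matched-taxon frequencies against the
    whole-library composition. Zero observed categories contribute 0."""
    cats = sorted(reference_taxa_counts)
    if set(matched_taxa_counts) - set(cats):
        raise ValueError("matched categories outside the reference universe")
    ref = np.array([reference_taxa_counts[c] for c in cats], dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference counts must all be positive")
    obs = np.array([matched_taxa_counts.get(c, 0) for c in cats], dtype=float)
    total = obs.sum()
    if total == 0:
        raise ValueError("no matched observations")
    expected = ref / ref.sum() * total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = float(2.0 * terms.sum())
    df = len(cats) - 1
    p = float(chi2.sf(g, df))
    return g, df, p
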