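"""Phylotype (OTU) clustering at a fixed identity threshold.

Sequences are grouped by greedy centroid clustering: unique sequences are
processed in order of decreasing duplicate abundance (ties broken
lexicographically by id) and each joins the first existing centroid whose
pairwise identity reaches the threshold, otherwise it founds a new OTU.
Identity is computed from a global alignment (match 1, mismatch 0, linear
gap -1) as matching columns over aligned columns, excluding terminal-gap
columns (clone reads are uniformly trimmed, so end overhangs are artifacts)
and counting internal gap columns as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .io import SampleMetadata, SequenceRecord

__all__ = ["OTUTable", "pairwise_identity", "cluster_otus", "build_otu_table"]


def _make_aligner(match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    # free end gaps: terminal overhangs are trimming artifacts
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Bio.Align releases
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction of identical columns in a global alignment of ``a`` and ``b``.

    Terminal gap columns are excluded from the denominator; internal gap
    columns count as mismatches. Symmetric in its arguments.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("empty sequence")
    # canonical argument order: co-optimal alignments can differ in identity,
    # so fix the orientation to make the function exactly symmetric
    if a.sequence > b.sequence:
        a, b = b, a
    aln = _ALIGNER.align(a.sequence, b.sequence)[0]
    sa, sb = aln[0], aln[1]
    # trim terminal gap columns on either end
    start = 0
    end = len(sa)
    while start < end and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols == 0:
        return 0.0
    matches = sum(1 for i in range(start, end) if sa[i] == sb[i])
    return matches / cols


def _hamming_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass
class OTUTable:
    """Sample x OTU count table with representatives and membership."""

    otu_ids: list[str]
    counts: pd.DataFrame  # rows = OTUs, columns = samples, int
    representative: Mapping[str, SequenceRecord]
    member_ids: Mapping[str, list[str]]
    metadata: list[SampleMetadata]

    def __post_init__(self) -> None:
        assert list(self.counts.index) == self.otu_ids
        assert (self.counts.to_numpy() >= 0).all()

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def sources(self) -> dict[str, str]:
        return {m.sample_id: m.source for m in self.metadata}

    def counts_by_source(self) -> pd.DataFrame:
        """Pool sample columns by source group."""
        src = self.sources()
        return self.counts.T.groupby(lambda s: src[s]).sum().T

    def write(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")


def cluster_otus(
    seqs: Sequence[SequenceRecord],
    threshold: float = 0.99,
) -> dict[str, list[str]]:
    """Greedy centroid clustering; returns centroid id -> member sequence ids.

    Deterministic for fixed input: unique sequences are visited in order of
    decreasing exact-duplicate abundance, ties by lexical id of the earliest
    member. A banded edit-distance prefilter (edlib) skips centroids that
    provably cannot reach the threshold: any alignment with edit distance
    ``ed`` has identity <= 1 - ed/(len(a)+len(b)), so ``ed`` beyond
    ``(1-t)*(len(a)+len(b))`` cannot pass. For equal-length pairs whose
    Hamming identity already reaches the threshold the alignment is skipped
    (under match 1/mismatch 0/gap -1 scoring the optimal alignment's
    identity is >= the Hamming identity: score >= gapless score implies
    matches' - gaps >= matches, and (m+g)/(L+g) >= m/L for m <= L).
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")

    groups: dict[str, list[str]] = {}
    for rec in seqs:
        groups.setdefault(rec.sequence, []).append(rec.id)
    uniq = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))

    centroids: list[SequenceRecord] = []
    members: dict[str, list[str]] = {}
    for sequence, ids in uniq:
        rec = SequenceRecord(min(ids), sequence)
        assigned = None
        for cen in centroids:
            max_ed = int((1 - threshold) * (len(sequence) + len(cen.sequence)))
            if (
                len(sequence) == len(cen.sequence)
                and _hamming_identity(sequence, cen.sequence) >= threshold
            ):
                assigned = cen.id
                break
            ed = edlib.align(sequence, cen.sequence, mode="NW", k=max_ed)[
                "editDistance"
            ]
            if ed == -1:  # exceeds band: cannot reach threshold
                continue
            if pairwise_identity(rec, cen) >= threshold:
                assigned = cen.id
                break
        if assigned is None:
            centroids.append(rec)
            members[rec.id] = sorted(ids)
        else:
            members[assigned] = sorted(members[assigned] + ids)
    return members


def build_otu_table(
    assignments: Mapping[str, list[str]],
    seqs: Sequence[SequenceRecord],
    metadata: Sequence[SampleMetadata],
    sample_of: Mapping[str, str] | None = None,
) -> OTUTable:
    """Assemble the OTU x sample count table from cluster assignments.

    ``sample_of`` maps sequence id -> sample id; when omitted, sequence ids
    of the form ``<sample>_<n>`` are split on the last underscore.
    """
    seq_by_id = {s.id: s for s in seqs}
    sample_ids = [m.sample_id for m in metadata]
    known = set(sample_ids)

    def _sample(seq_id: str) -> str:
        if sample_of is not None:
            try:
                return sample_of[seq_id]
            except KeyError:
                raise KeyError(f"sequence {seq_id!r} has no sample mapping")
        sid = seq_id.rsplit("_", 1)[0]
        if sid not in known:
            raise KeyError(f"sequence {seq_id!r}: unknown sample {sid!r}")
        return sid

    otu_ids = sorted(assignments, key=lambda c: (-len(assignments[c]), c))
    counts = np.zeros((len(otu_ids), len(sample_ids)), dtype=int)
    col = {s: j for j, s in enumerate(sample_ids)}
    for i, centroid in enumerate(otu_ids):
        for seq_id in assignments[centroid]:
            s = _sample(seq_id)
            if s not in col:
                raise KeyError(f"sequence {seq_id!r}: unknown sample {s!r}")
            counts[i, col[s]] += 1
    df = pd.DataFrame(counts, index=otu_ids, columns=sample_ids)
    return OTUTable(
        otu_ids=otu_ids,
        counts=df,
        representative={c: seq_by_id[c] for c in otu_ids},
        member_ids={c: list(assignments[c]) for c in otu_ids},
        metadata=list(metadata),
    )
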