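"""Synthetic communities, sequences, trees and electropherograms.

The generator emulates the statistical structure the analysis pipeline
assumes: four source groups (two sponge hosts, one tunicate, seawater)
with 9/3/3/9 replicate samples of 15 clones each; one dominant
host-specific phylotype per sponge host present in every sample of that
host at 25-55% of its clones; a generalist fraction drawn from a shared
seawater pool; a singleton-rich log-series tail; and capillary
electropherograms with size-dependent Gaussian T-RF drift, baseline noise
peaks and out-of-window fragments.

Sequence construction guarantees that 99% clustering recovers the planted
partition: every pair of phylotype ancestors differs at >= 24 of 600
positions (mutation sets of 15 positions with pairwise overlap capped at
3), while members carry at most 2 extra substitutions, so within-phylotype
identity is >= 99.3% and between-phylotype identity is <= 96.7%.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream,
so a fixed seed reproduces every file byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import OTUAnnotation
from .digest import BUILTIN_ENZYMES, ReferenceTRFDatabase, predict_trf
from .io import (
    PeakProfile,
    SampleMetadata,
    SequenceRecord,
    write_fasta,
    write_json,
    write_peak_table,
    write_sample_metadata,
)
from .matching import ToleranceBins, tolerance_for
from .otus import OTUTable

__all__ = [
    "SimulationParams",
    "simulate_community",
    "simulate_sequences",
    "simulate_electropherograms",
    "simulate_tree",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationParams:
    """Default values reproduce the replication and community structure of
    the study design the pipeline targets."""

    sources: tuple[tuple[str, int], ...] = (
        ("Hymeniacidon", 9),
        ("Haliclona", 3),
        ("Didemnum", 3),
        ("seawater", 9),
    )
    seawater_source: str = "seawater"
    clones_per_sample: int = 15
    # per-host dominant clone fractions (sponge hosts only; the tunicate
    # community is even, with no dominant phylotype)
    dominant_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"Hymeniacidon": 0.34, "Haliclona": 0.51}
    )
    # per-host fraction of non-dominant clones drawn from the shared
    # seawater pool
    generalist_fraction: Mapping[str, float] = field(
        default_factory=lambda: {
            "Hymeniacidon": 0.27,
            "Haliclona": 0.45,
            "Didemnum": 0.55,
        }
    )
    n_seawater_otus: int = 150
    n_specialist_otus: Mapping[str, int] = field(
        default_factory=lambda: {"Hymeniacidon": 60, "Haliclona": 20, "Didemnum": 50}
    )
    log_series_theta: float = 0.9999  # singleton-rich abundance tail
    seq_length: int = 600
    n_ancestor_mutations: int = 15
    max_shared_positions: int = 3
    max_member_mutations: int = 2
    enzymes: tuple[str, ...] = ("HaeIII", "MspI", "RsaI")
    detection_window: tuple[float, float] = (100.0, 500.0)
    p_site: float = 0.85  # per enzyme: chance a phylotype carries a site
    p_in_window: float = 0.8  # planted site falls inside the sizing range
    drift_a: float = 0.2  # bp, drift sd intercept
    drift_b: float = 0.004  # bp drift sd per bp of fragment length
    noise_peaks: int = 3
    total_fluorescence: tuple[float, float] = (20000.0, 60000.0)


def _log_series_weights(n: int, theta: float) -> np.ndarray:
    k = np.arange(1, n + 1, dtype=float)
    w = theta**k / k
    return w / w.sum()


def simulate_community(
    params: SimulationParams = SimulationParams(), seed: int = 0
) -> tuple[pd.DataFrame, list[SampleMetadata], dict]:
    """Draw a sample x phylotype clone-count table plus ground truth.

    Returns (counts DataFrame rows=OTUs cols=samples, metadata, truth).
    ``truth`` records each phylotype's pool of origin, its environmental
    identity annotation, and the realized per-host category implied by the
    classification rules, so downstream recovery can be scored exactly.
    """
    rng = np.random.default_rng(seed)
    hosts = [s for s, _ in params.sources if s != params.seawater_source]

    otu_pool: dict[str, dict] = {}

    def new_otu(pool: str, env_identity: float) -> str:
        oid = f"OTU{len(otu_pool) + 1:04d}"
        otu_pool[oid] = {"pool": pool, "env_identity": round(env_identity, 4)}
        return oid

    sea_otus = [
        new_otu("seawater", rng.uniform(0.985, 1.0))
        for _ in range(params.n_seawater_otus)
    ]
    sea_w = _log_series_weights(params.n_seawater_otus, params.log_series_theta)
    dominant: dict[str, str] = {}
    specialists: dict[str, list[str]] = {}
    spec_w: dict[str, np.ndarray] = {}
    for host in hosts:
        if host in params.dominant_fraction:
            dominant[host] = new_otu(f"dominant:{host}", rng.uniform(0.90, 0.975))
        n_spec = params.n_specialist_otus[host]
        specialists[host] = [
            new_otu(f"specialist:{host}", rng.uniform(0.90, 0.975))
            for _ in range(n_spec)
        ]
        spec_w[host] = _log_series_weights(n_spec, params.log_series_theta)

    samples: list[SampleMetadata] = []
    columns: dict[str, dict[str, int]] = {}
    for source, n_samples in params.sources:
        for i in range(1, n_samples + 1):
            sid = f"{source.upper()}{i}"
            samples.append(
                SampleMetadata(
                    sample_id=sid,
                    source=source,
                    location=f"platform{1 + (i - 1) % 5}",
                    n_clones=params.clones_per_sample,
                )
            )
            col: dict[str, int] = {}
            n = params.clones_per_sample
            if source == params.seawater_source:
                draws = rng.choice(sea_otus, size=n, p=sea_w)
            else:
                n_dom = 0
                if source in dominant:
                    n_dom = int(round(params.dominant_fraction[source] * n))
                    col[dominant[source]] = n_dom
                g = params.generalist_fraction[source]
                rest = []
                for _ in range(n - n_dom):
                    if rng.random() < g:
                        rest.append(rng.choice(sea_otus, p=sea_w))
                    else:
                        rest.append(rng.choice(specialists[source], p=spec_w[source]))
                draws = np.array(rest)
            for oid in draws:
                col[oid] = col.get(oid, 0) + 1
            columns[sid] = col

    otu_ids = [o for o in otu_pool if any(o in c for c in columns.values())]
    counts = pd.DataFrame(
        0, index=otu_ids, columns=[m.sample_id for m in samples], dtype=int
    )
    for sid, col in columns.items():
        for oid, k in col.items():
            counts.loc[oid, sid] = k
    # order phylotypes by total abundance, then id, matching the clustering
    # convention
    order = sorted(otu_ids, key=lambda o: (-counts.loc[o].sum(), o))
    counts = counts.loc[order]

    truth = {
        "otus": {o: otu_pool[o] for o in order},
        "dominant": dominant,
        "category": _realized_categories(counts, samples, otu_pool, hosts, params),
        "params": {"seed": seed},
    }
    return counts, samples, truth


def _realized_categories(counts, samples, otu_pool, hosts, params):
    """Apply the classification rules to the planted table (the ground truth
    the pipeline is asked to recover)."""
    src = {m.sample_id: m.source for m in samples}
    sea = [s for s in counts.columns if src[s] == params.seawater_source]
    out: dict[str, dict[str, str]] = {h: {} for h in hosts}
    for host in hosts:
        cols = [s for s in counts.columns if src[s] == host]
        host_total = counts[cols].to_numpy().sum()
        for oid in counts.index:
            row = counts.loc[oid]
            if row[cols].sum() == 0:
                continue
            in_sea = bool((row[sea] > 0).any())
            env = otu_pool[oid]["env_identity"]
            n_present = int((row[cols] > 0).sum())
            frac = row[cols].sum() / host_total
            if in_sea or env > 0.98:
                cat = "generalist"
            elif n_present == len(cols) and frac > 0.25:
                cat = "dominant specialist"
            elif n_present >= 2:
                cat = "common specialist"
            else:
                cat = "rare specialist"
            out[host][oid] = cat
    return out


_MOTIFS = ("GGCC", "CCGG", "GTAC")
_BASES = np.array(list("ACGT"))


def _scrub_motifs(seq: list[str], rng: np.random.Generator) -> None:
    """Mutate bases until no built-in recognition motif occurs."""
    s = "".join(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for motif in _MOTIFS:
            i = s.find(motif)
            if i >= 0:
                j = i + int(rng.integers(len(motif)))
                current = seq[j]
                seq[j] = rng.choice([b for b in "ACGT" if b != current])
                changed = True
                break


def simulate_sequences(
    counts: pd.DataFrame,
    truth: dict,
    params: SimulationParams = SimulationParams(),
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Generate clone sequences realizing the planted community.

    Returns (records, sample_of) where ids are ``<sample>_<k>`` and
    ``sample_of`` maps each clone id to its sample. Restriction sites are
    planted per phylotype so predicted T-RFs are controllable; the motif-free
    root guarantees the planted site is the first occurrence in the
    ancestor.
    """
    rng = np.random.default_rng(seed + 1)
    L = params.seq_length
    root = list(rng.choice(_BASES, size=L))
    _scrub_motifs(root, rng)

    otu_ids = list(counts.index)
    mutation_sets: list[set[int]] = []
    ancestors: dict[str, list[str]] = {}
    planted: dict[str, dict[str, int | None]] = {}
    for oid in otu_ids:
        # choose planted sites first so ancestor mutations can avoid them
        planted[oid] = {}
        sites: list[tuple[str, int]] = []
        used: list[int] = []
        for enz_name in params.enzymes:
            enz = BUILTIN_ENZYMES[enz_name]
            if rng.random() >= params.p_site:
                planted[oid][enz_name] = None
                continue
            lo, hi = params.detection_window
            if rng.random() < params.p_in_window:
                trf = int(rng.integers(int(lo), int(hi) - 19))
            else:
                trf = int(rng.integers(20, int(lo) - 1))
            start = trf - enz.cut_offset  # 0-based site start
            if any(abs(start - u) < 8 for u in used) or start < 0:
                planted[oid][enz_name] = None
                continue
            used.append(start)
            sites.append((enz.recognition, start))
            planted[oid][enz_name] = trf
        site_cover = {
            start + k for rec, start in sites for k in range(len(rec))
        }
        candidates = np.array(sorted(set(range(L)) - site_cover))
        while True:
            positions = set(
                rng.choice(candidates, size=params.n_ancestor_mutations,
                           replace=False).tolist()
            )
            if all(
                len(positions & prev) <= params.max_shared_positions
                for prev in mutation_sets
            ):
                break
        mutation_sets.append(positions)
        seq = list(root)
        for pos in positions:
            seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
        for rec, start in sites:
            seq[start : start + len(rec)] = list(rec)
        ancestors[oid] = seq

    records: list[SequenceRecord] = []
    sample_of: dict[str, str] = {}
    clone_otu: dict[str, str] = {}
    for sid in counts.columns:
        k = 0
        for oid in otu_ids:
            for _ in range(int(counts.loc[oid, sid])):
                k += 1
                seq = list(ancestors[oid])
                n_mut = int(rng.choice(
                    params.max_member_mutations + 1,
                    p=_member_mutation_probs(params.max_member_mutations),
                ))
                for pos in rng.choice(L, size=n_mut, replace=False):
                    seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
                cid = f"{sid}_{k}"
                records.append(SequenceRecord(cid, "".join(seq)))
                sample_of[cid] = sid
                clone_otu[cid] = oid
    truth["planted_sites"] = planted
    truth["clone_otu"] = clone_otu
    return records, sample_of


def _member_mutation_probs(max_mut: int) -> np.ndarray:
    # half the clones are exact copies of the ancestor; the rest carry a
    # couple of sequencing/intra-population substitutions
    base = np.array([0.5] + [0.5 / max_mut] * max_mut)
    return base / base.sum()


def simulate_electropherograms(
    db: ReferenceTRFDatabase,
    table: OTUTable,
    params: SimulationParams = SimulationParams(),
    seed: int = 0,
    drift: bool = True,
    noise: bool = True,
) -> list[PeakProfile]:
    """Render peak profiles from the reference predictions.

    Each phylotype present in a sample contributes one peak per enzyme at
    its predicted size plus Gaussian drift with sd = a + b*L, truncated at
    half the applicable tolerance so drifted peaks stay matchable.
    Out-of-window predictions are rendered too (they exercise the window
    filter), and uniform low-fluorescence noise peaks are added.
    """
    rng = np.random.default_rng(seed + 2)
    bins = ToleranceBins()
    profiles: list[PeakProfile] = []
    for sid in table.samples:
        total = float(rng.uniform(*params.total_fluorescence))
        col = table.counts[sid]
        present = col[col > 0]
        rel = present / present.sum()
        for enzyme in db.enzymes:
            peaks: dict[float, float] = {}
            for oid, frac in rel.items():
                pred = db.entries[oid][enzyme]
                if pred is None:
                    continue
                size = float(pred)
                if drift:
                    sd = params.drift_a + params.drift_b * size
                    cap = tolerance_for(size, bins) / 2.0
                    delta = float(np.clip(rng.normal(0.0, sd), -cap, cap))
                    size = size + delta
                size = round(size, 2)
                peaks[size] = peaks.get(size, 0.0) + float(frac) * total
            if noise:
                for _ in range(params.noise_peaks):
                    size = round(float(rng.uniform(50.0, 550.0)), 2)
                    if size not in peaks:
                        peaks[size] = float(rng.uniform(0.0005, 0.005)) * total
            profiles.append(
                PeakProfile(sample_id=sid, enzyme=enzyme,
                            peaks=sorted(peaks.items()))
            )
    return profiles


def simulate_tree(
    otu_ids: Sequence[str],
    truth: dict,
    seed: int = 0,
) -> "dendropy.Tree":
    """Random tree in which each host's specialist phylotypes form a clade
    while generalist/seawater phylotypes scatter in the backbone."""
    import dendropy

    rng = np.random.default_rng(seed + 3)
    pools = {o: truth["otus"][o]["pool"] for o in otu_ids}
    clades: dict[str, list[str]] = {}
    backbone: list[str] = []
    for oid in otu_ids:
        pool = pools[oid]
        if pool.startswith(("dominant:", "specialist:")):
            clades.setdefault(pool.split(":", 1)[1], []).append(oid)
        else:
            backbone.append(oid)

    def join(newicks: list[str]) -> str:
        newicks = list(newicks)
        while len(newicks) > 1:
            i, j = sorted(rng.choice(len(newicks), size=2, replace=False))
            b = newicks.pop(j)
            a = newicks.pop(i)
            l1, l2 = rng.uniform(0.02, 0.2, size=2)
            newicks.append(f"({a}:{l1:.4f},{b}:{l2:.4f})")
        return newicks[0]

    subtrees = []
    for host in sorted(clades):
        tips = clades[host]
        if len(tips) == 1:
            subtrees.append(tips[0])
        else:
            # short internal branches: a tight host-specific clade
            inner = join(tips)
            subtrees.append(inner)
    subtrees.extend(backbone)
    if len(subtrees) == 1:
        newick = f"({subtrees[0]}:0.1);"
    else:
        newick = join(subtrees) + ";"
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def simulate_dataset(
    params: SimulationParams = SimulationParams(),
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict:
    """Full synthetic dataset; optionally written in the pipeline's own
    file formats (seqs.fa, samples.tsv, peaks.csv, tree.nwk, truth.json)."""
    from .digest import build_reference_db

    counts, samples, truth = simulate_community(params, seed)
    records, sample_of = simulate_sequences(counts, truth, params, seed)
    # representative = first realized clone of each phylotype (record order
    # mirrors the column-major generation order of simulate_sequences)
    seen: dict[str, SequenceRecord] = {}
    idx = 0
    for sid in counts.columns:
        col = counts[sid]
        for oid in counts.index:
            for _ in range(int(col[oid])):
                idx += 1
                if oid not in seen:
                    seen[oid] = records[idx - 1]
    db = build_reference_db(
        {oid: seen[oid] for oid in counts.index},
        enzymes=params.enzymes,
        window=params.detection_window,
    )
    table = OTUTable(
        otu_ids=list(counts.index),
        counts=counts,
        representative=seen,
        member_ids={o: [] for o in counts.index},
        metadata=samples,
    )
    profiles = simulate_electropherograms(db, table, params, seed)
    tree = simulate_tree(list(counts.index), truth, seed)
    # keyed both by planted phylotype id and by clone id, so the pipeline
    # can look annotations up through cluster members
    annotations = {
        o: OTUAnnotation(o, truth["otus"][o]["env_identity"])
        for o in counts.index
    }
    annotations.update(
        {
            cid: OTUAnnotation(cid, truth["otus"][oid]["env_identity"])
            for cid, oid in truth["clone_otu"].items()
        }
    )
    out = {
        "counts": counts,
        "metadata": samples,
        "truth": truth,
        "records": records,
        "sample_of": sample_of,
        "db": db,
        "profiles": profiles,
        "tree": tree,
        "annotations": annotations,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, outdir / "seqs.fa")
        write_sample_metadata(samples, outdir / "samples.tsv")
        write_peak_table(profiles, outdir / "peaks.csv")
        tree.write(path=str(outdir / "tree.nwk"), schema="newick",
                   unquoted_underscores=True)
        write_json(
            {
                "otus": truth["otus"],
                "dominant": truth["dominant"],
                "category": truth["category"],
                "planted_sites": truth["planted_sites"],
            },
            outdir / "truth.json",
        )
        ct = counts.copy()
        ct.index.name = "otu_id"
        ct.to_csv(outdir / "true_otu_table.tsv", sep="\t")
    return out
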