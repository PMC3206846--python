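"""Host-specificity classification of phylotypes.

A host-associated phylotype is a *generalist* if it is shared with the
seawater community or is closely related (>98% identity) to free-living
environmental sequences; otherwise it is a *specialist*, sub-classified by
prevalence and abundance within its host:

* dominant — present in every host sample and accounting for more than a
  quarter of the host's clones;
* common — present in at least two host samples;
* rare — present in a single host sample.

Environmental identity annotations are supplied externally (e.g. from
prior BLAST results); a missing annotation leaves the phylotype
specialist-eligible but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .otus import OTUTable

__all__ = ["OTUAnnotation", "ClassificationResult", "classify_otu", "classify_all"]

ENV_IDENTITY_CUTOFF = 0.98  # >98% identity to free-living references => generalist
DOMINANT_FRACTION = 0.25


@dataclass(frozen=True)
class OTUAnnotation:
    otu_id: str
    closest_env_identity: float | None = None  # fraction in [0, 1]
    taxon: str | None = None

    def __post_init__(self) -> None:
        v = self.closest_env_identity
        if v is not None and not 0.0 <= v <= 1.0:
            raise ValueError(f"{self.otu_id}: identity {v} outside [0, 1]")


@dataclass(frozen=True)
class ClassificationResult:
    otu_id: str
    host: str
    category: str  # dominant specialist | common specialist | rare specialist | generalist
    present_in_all_host_samples: bool
    clone_fraction: float  # fraction of the host's clones
    n_host_samples_present: int
    shared_with_seawater: bool
    env_identity: float | None
    flags: tuple[str, ...] = field(default_factory=tuple)


def classify_otu(
    otu_id: str,
    table: OTUTable,
    annotation: OTUAnnotation | None,
    host: str,
    seawater_source: str = "seawater",
    other_hosts: Sequence[str] = (),
) -> ClassificationResult:
    """Classify one phylotype with respect to one host source."""
    src = table.sources()
    host_samples = [s for s in table.samples if src[s] == host]
    sea_samples = [s for s in table.samples if src[s] == seawater_source]
    if not host_samples:
        raise ValueError(f"host {host!r} absent from metadata")
    row = table.counts.loc[otu_id]
    host_counts = row[host_samples]
    if host_counts.sum() == 0:
        raise ValueError(f"{otu_id} absent from host {host!r}")

    n_present = int((host_counts > 0).sum())
    host_total = int(table.counts[host_samples].to_numpy().sum())
    frac = float(host_counts.sum()) / host_total
    in_sea = bool((row[sea_samples] > 0).any()) if sea_samples else False
    env_id = annotation.closest_env_identity if annotation else None

    flags: list[str] = []
    if env_id is None:
        flags.append("no annotation")
    if any(
        (row[[s for s in table.samples if src[s] == h]] > 0).any()
        for h in other_hosts
        if h != host
    ):
        flags.append("multi-host")

    if in_sea or (env_id is not None and env_id > ENV_IDENTITY_CUTOFF):
        category = "generalist"
    elif n_present == len(host_samples) and frac > DOMINANT_FRACTION:
        category = "dominant specialist"
    elif n_present >= 2:
        category = "common specialist"
    else:
        category = "rare specialist"

    return ClassificationResult(
        otu_id=otu_id,
        host=host,
        category=category,
        present_in_all_host_samples=n_present == len(host_samples),
        clone_fraction=frac,
        n_host_samples_present=n_present,
        shared_with_seawater=in_sea,
        env_identity=env_id,
        flags=tuple(flags),
    )


CATEGORIES = (
    "dominant specialist",
    "common specialist",
    "rare specialist",
    "generalist",
)


def classify_all(
    table: OTUTable,
    annotations: Mapping[str, OTUAnnotation],
    hosts: Sequence[str],
    seawater_source: str = "seawater",
) -> dict[str, dict]:
    """Classify every phylotype of every host; tally counts and clone
    fractions per category (fractions partition each host's clones)."""
    src = table.sources()
    out: dict[str, dict] = {}
    for host in hosts:
        host_samples = [s for s in table.samples if src[s] == host]
        present = table.counts.index[
            (table.counts[host_samples] > 0).any(axis=1)
        ]
        results = [
            classify_otu(
                otu,
                table,
                annotations.get(otu),
                host,
                seawater_source=seawater_source,
                other_hosts=[h for h in hosts if h != host],
            )
            for otu in present
        ]
        tallies = {
            cat: {
                "n_otus": sum(1 for r in results if r.category == cat),
                "clone_fraction": sum(
                    r.clone_fraction for r in results if r.category == cat
                ),
            }
            for cat in CATEGORIES
        }
        singleton_otus = [
            r for r in results if table.counts.loc[r.otu_id, host_samples].sum() == 1
        ]
        out[host] = {
            "results": results,
            "tallies": tallies,
            "n_otus": len(results),
            "singletons": {
                "n": len(singleton_otus),
                "n_env_related": sum(
                    1
                    for r in singleton_otus
                    if r.env_identity is not None
                    and r.env_identity > ENV_IDENTITY_CUTOFF
                ),
            },
        }
    return out
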