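# symprofiler

Clone-library and T-RFLP profiling of host-associated bacterial communities.

Marine sponges and other benthic invertebrates host bacterial consortia
that must be distinguished from seawater bacteria, prey, and transient
colonists. The classical evidence combines two views of the same 16S rRNA
gene pool: replicated clone libraries (sequences, grouped into phylotypes
at ≥99% identity) and terminal restriction fragment length polymorphism
(T-RFLP) fingerprints, in which the fluorescently labeled 5′ fragment
produced by the first cut of a restriction enzyme is sized on a capillary
sequencer. `symprofiler` implements that entire computational workflow as
a tested, reusable library and command-line tool:

- **OTU clustering** — greedy centroid clustering of clone sequences at a
  fixed identity threshold (default 0.99), identity from a global
  alignment with free end gaps.
- **In-silico digestion** — predicted terminal restriction fragment (T-RF)
  per phylotype per enzyme (HaeIII, MspI, RsaI built in), assembled into a
  reference database with a 100–500 bp detection window.
- **T-RFLP processing** — variable-threshold standardization of raw peak
  profiles (the smallest percentage threshold decoupling peak count from
  total fluorescence) and consensus alignment of T-RFs across samples.
- **Reference matching** — empirical T-RFs matched to predictions inside
  size-dependent tolerance bins (±1.0 bp ≤200 bp, ±1.5 bp ≤400 bp,
  ±4.0 bp beyond), per-phylotype T-RFLP signatures classified as unique,
  shared or undetected.
- **Community statistics** — S_obs, Chao1 = S + F₁²/2F₂, Shannon H′
  (nats), evenness J = H′/ln S, analytic rarefaction, Bray–Curtis on
  √-transformed relative abundances, non-metric MDS, ANOSIM
  R = (r̄_B − r̄_W)/(M/2), likelihood-ratio (G) tests.
- **Phylogenetic metrics** — Tajima–Nei (1984) distances, AMOVA F_ST,
  LIBSHUFF coverage-curve comparison, the parsimony P-test, and NRI/NTI
  dispersion z-scores.
- **Symbiont classification** — host-exclusive, environmentally divergent
  phylotypes become dominant/common/rare specialists; seawater-shared or
  >98%-environmental phylotypes become generalists.
- **Synthetic data** — a seeded generator reproducing the study structure
  the analysis assumes (4 sources with 9/3/3/9 replicate samples of 15
  clones, one dominant specialist per sponge host, singleton-rich tails,
  size-dependent T-RF drift), so every stage is testable end to end
  without downloads.

## Worked example

```python
from symprofiler.simulate import simulate_dataset
from symprofiler.pipeline import run_pipeline

ds = simulate_dataset(seed=1)            # 24 samples x 15 clones
res = run_pipeline(ds["records"], ds["sample_of"], ds["metadata"],
                   ds["profiles"], annotations=ds["annotations"],
                   hosts=["Hymeniacidon", "Haliclona", "Didemnum"],
                   n_perm=999, seed=1)

print(len(res["table"].otu_ids))          # 120 phylotypes from 360 clones
print(round(res["anosim_otu"].R, 3), res["anosim_otu"].p)   # 0.947 0.001
print(res["signature_summary"]["resolution_counts"])
# {'unique': 108, 'shared': 6, 'undetected': 6}
dom = [r.otu_id for r in res["classification"]["Haliclona"]["results"]
       if r.category == "dominant specialist"]
print(dom)                                # ['HALICLONA1_6']
```

The ANOSIM R of 0.947 at p = 0.001 says that between-source Bray–Curtis
ranks overwhelm within-source ranks: the four communities are distinct.
The single dominant specialist recovered for the *Haliclona*-like host is
the planted one (its most abundant clone is the cluster centroid). Of the
120 phylotypes, 108 present unique T-RFLP signatures, 6 share a signature
with another phylotype, and 6 have no in-window T-RF at all.

The same chain is available from the shell:

```bash
symprofiler simulate --seed 1 --out sim/
symprofiler cluster --fasta sim/seqs.fa --metadata sim/samples.tsv --out otus.tsv
symprofiler digest --fasta otus_reps.fa --out refdb.json
symprofiler standardize --peaks sim/peaks.csv --enzyme HaeIII --out filtered.csv
symprofiler align-trfs --peaks filtered.csv --enzyme HaeIII --out trf_HaeIII.tsv
symprofiler anosim --matrix otus.tsv --groups sim/samples.tsv --perms 999
```

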