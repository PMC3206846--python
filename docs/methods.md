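# Methods

This note records the models, conventions and numerical choices behind
`symprofiler`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Phylotype clustering

Sequences are grouped into operational taxonomic units (OTUs, "phylotypes")
by greedy centroid clustering at a fixed identity threshold, default 0.99.
Unique sequences are visited in order of decreasing exact-duplicate
abundance (ties broken by the lexically smallest member id); each joins the
first centroid whose pairwise identity reaches the threshold, otherwise it
founds a new OTU with itself as representative. The procedure is
deterministic for a fixed input, and re-clustering the representatives at
the same threshold is idempotent.

Pairwise identity is computed from a global alignment (match 1, mismatch 0,
linear gap −1, free end gaps) as matching columns over aligned columns,
with terminal-gap columns excluded from the denominator — clone reads are
uniformly trimmed, so end overhangs carry no signal — and internal gap
columns counted as mismatches. Because co-optimal alignments can differ
slightly in identity, the two sequences are put in a canonical order before
aligning, which makes the function exactly symmetric. Clustering uses two
exact-safe accelerations: a banded edit-distance prefilter (any alignment
with edit distance *ed* has identity ≤ 1 − *ed*/(len a + len b), so pairs
beyond the band are skipped without aligning) and a Hamming fast-accept for
equal-length pairs (under this scoring the optimal alignment's identity is
never below the Hamming identity).

## In-silico digestion

The predicted terminal restriction fragment (T-RF) of a phylotype for an
enzyme is the labeled 5′ fragment left by the earliest recognition-site
occurrence: trf = (site start − 1) + cut offset + primer offset. Built-in
enzymes use the standard REBASE cut positions — HaeIII GG^CC (offset 2),
MspI C^CGG (offset 1), RsaI GT^AC (offset 2). Degenerate IUPAC codes in a
recognition sequence expand to character classes; ambiguity codes in the
*scanned sequence* (e.g. N) never match, a conservative rule that avoids
phantom sites. All built-in sites are palindromic, so only the sense strand
is searched; a non-palindromic user enzyme triggers a dual-strand search
taking the shorter labeled fragment. The detection window (default
100–500 bp, the accurate sizing range of the capillary platform) is
inclusive at both ends. The primer offset defaults to 0 — predictions are
made from the first base of the provided sequence — and is configurable for
reconciling trimmed reads with fragments that run from the labeled primer.

## T-RFLP standardization and alignment

Raw electropherogram profiles are standardized by a variable-threshold grid
search. For a candidate percentage P, each profile is filtered to a fixed
point: drop peaks below P × current total fluorescence, recompute the
total, repeat. The chosen P is the smallest at which the per-sample
retained-peak count is statistically decoupled from total fluorescence
(two-sided Pearson test, p ≥ 0.05); zero variance in either variable counts
as decoupled. The default grid is 0–5% in 0.01% steps. Peaks outside the
detection window are removed before thresholding. Grid, alpha and the
correlation test are configurable.

Filtered peaks are pooled across samples, sorted, and binned greedily left
to right with a running-mean rule: a peak joins the open bin while its size
is within the consensus window (default 0.5 bp) of the bin's current mean
size, with a tie at exactly the window boundary joining the bin. Binning is
therefore order-invariant and raising the window can only merge bins. The
matrix is row-normalized (relative mode, rows sum to 1) or binarized.
One profile per sample and enzyme is assumed: replicate PCR products are
taken to be pooled before digestion.

## Matching and T-RFLP signatures

Capillary sizing drifts from the true fragment length, and the drift grows
with size, so matches are accepted inside size-dependent tolerance bins:
±1.0 bp for predictions up to 200 bp, ±1.5 bp for 201–400 bp, ±4.0 bp above
400 bp. Boundary sizes (exactly 200 or 400) take the smaller tolerance. A
prediction matches the nearest qualifying empirical bin, ties going to the
smaller size. Only in-window predictions participate. A phylotype's T-RFLP
signature is its set of matched (enzyme, bin) pairs; signatures are unique
(no other phylotype has the identical set), shared, or undetected (empty).
Matching is study-wide rather than sample-aware: an empirical bin anywhere
in the aligned matrix can support a match. Sequence relatedness of
phylotypes sharing a signature is summarized as mean pairwise divergence
(100 × (1 − identity)) per shared group, stratified by the number of
enzymes in the signature, with the standard error taken over group means.

## Community statistics

Alpha diversity per sample: observed richness S_obs; classic Chao1
S_obs + F₁²/(2F₂) with the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)) when no doubletons exist; Shannon H′ in natural
log; evenness J = H′/ln S_obs, reported as missing for single-OTU samples.
Rarefaction uses the analytic hypergeometric expectation
E[S_m] = Σᵢ (1 − C(N−Nᵢ, m)/C(N, m)). Bray–Curtis dissimilarity is computed
on square-root-transformed relative abundances (or presence/absence); a
pair of empty samples is assigned distance 0 with a warning rather than
NaN. Non-metric MDS minimizes Kruskal stress-1 (20 random restarts, 500
iterations, 1e−7 stress tolerance, seeded; delegated to scikit-learn).

ANOSIM ranks all n(n−1)/2 dissimilarities with mid-rank ties and reports
R = (r̄_between − r̄_within)/(M/2); the p-value is the add-one one-sided
permutation tail (≥ observed) under random label reassignment, with an
exhaustive enumeration mode for small n. Post-hoc pairwise comparisons
carry both raw and Bonferroni-adjusted p-values. The likelihood-ratio
G statistic is 2 Σ O ln(O/E) with zero-count cells contributing nothing;
independence tests use df = (r−1)(c−1), goodness-of-fit tests df = k−1,
and chi-square upper tails throughout.

## Phylogenetic metrics

Tajima–Nei (1984) distance: d = −b̂ ln(1 − p/b̂) with
b̂ = (1 − Σgᵢ² + p²/ĥ)/2 and ĥ = Σᵢ<ⱼ x̂ᵢⱼ²/(2gᵢgⱼ), gap/ambiguity columns
pairwise-deleted; saturated pairs (p ≥ b̂) return +inf.

The P-test scores the parsimony length of the source label on a supplied
tree (Hartigan's generalization of the Fitch recurrence, exact on
multifurcations) against random tip-label permutations; small observed
lengths mean lineages sort by source.

NRI and NTI are z-scores of mean pairwise patristic distance (MPD) and
mean nearest-taxon distance (MNTD) against a tip-shuffle null: community
membership is redrawn from the supplied pool (default: all tips), with the
sample (n−1) standard deviation and the sign convention that clustering is
positive. A degenerate null (sd ≈ 0, e.g. community = pool, or a star
tree) leaves the index undefined rather than infinite.

LIBSHUFF compares two sequence libraries through coverage curves on a
distance grid (default 0–0.50 by 0.01): homologous coverage C_X(D) is the
fraction of X with another X member within D, heterologous C_XY(D)
substitutes the other library. The statistic ΔC_XY sums the squared
*positive* coverage deficit, Σ max(C_X − C_XY, 0)², so a library covered
at least as well by the other library as by itself — including the
degenerate case of an exact duplicate — scores zero; this one-sided
Cramér–von Mises form keeps ΔC ≥ 0 and zero exactly when Y explains X.
Significance comes from shuffling sequences between libraries, both
directions reported.

AMOVA decomposes squared distances hierarchically (sequences within
samples within sources) in the Excoffier style, with unbalanced-design
coefficients; F_ST is the among-source share of total molecular variance,
tested by permuting whole samples among sources with the add-one
convention. A source holding a single sample forces a two-level design
(sequences within sources, sequences permuted) with a warning.

## Symbiont classification

A host-associated phylotype is a generalist if it is observed in any
seawater sample or its closest environmental (free-living) identity
exceeds 0.98; identity exactly 0.98 (2% divergence) remains
specialist-eligible. Specialists are dominant (present in every host
sample and more than a quarter of the host's clones — fractions are
host-relative), common (≥2 host samples) or rare (1 sample). Environmental
identities are consumed as external annotations; no live database search
is performed. Missing annotations leave a phylotype specialist-eligible
with a "no annotation" flag; phylotypes shared between hosts but absent
from seawater are classified per host and flagged "multi-host".

## Synthetic data generator

The generator emulates the replication and community structure the
analysis assumes: four sources (two sponge hosts, a tunicate, seawater)
with 9/3/3/9 replicate samples of 15 clones; one dominant specialist per
sponge host, present in every host sample at ~34% and ~51% of clones
respectively; host-specific specialist pools and a shared seawater pool
with log-series abundance weights (θ = 0.9999 over pools of 150 seawater
and 60/20/50 specialist phylotypes), giving singleton-rich libraries
(~50–60% of phylotypes observed once); and per-host generalist fractions
of 0.27/0.45/0.55 drawn from the seawater pool. The tunicate community is
even, with no dominant phylotype.

Sequences are built so that 99% clustering provably recovers the planted
partition: each phylotype ancestor carries 15 substitutions relative to a
shared motif-free root at positions whose overlap with any other
ancestor's set is capped at 3 (so ancestors differ at ≥24 of 600
positions, ≤96% identity), while clone-level variants carry at most 2
further substitutions (≥99.3% within-phylotype identity). Restriction
sites are planted per phylotype (85% chance per enzyme, 80% of sites
inside the 100–500 bp window) after scrubbing the root of all recognition
motifs, so predicted T-RFs are controllable.

Electropherograms are rendered from the reference predictions: one peak
per present phylotype per enzyme at the predicted size plus Gaussian drift
with sd = 0.2 + 0.004·L bp — so ~1.8 bp at 400+ bp, mirroring the
size-dependent drift that motivates the widening tolerance bins —
truncated at half the applicable tolerance so drifted peaks stay
matchable; fluorescence proportional to relative abundance times a sample
total drawn from 20,000–60,000 units; plus three uniform low-fluorescence
noise peaks per profile, some below the sizing window. Trees place each
host's specialists in a clade and scatter the rest, so lineage-sorting and
dispersion tests have planted signal.

All randomness flows from a single seeded NumPy PCG64 generator; a fixed
seed reproduces every output file byte-for-byte. What the generator does
*not* emulate: PCR and cloning bias, chimeras, realistic 16S substitution
processes (divergence is controlled combinatorially, not evolved),
pseudo-gaps/indels, multi-dye artifacts, or partial digestion. Passing
tests therefore demonstrate correctness of the computational chain under
the stated community structure, not robustness to those wet-lab artifacts.

## Problem sizes and determinism

The default test and acceptance configurations use 24 samples × 15 clones
(360 sequences, 600 bp), reference databases of ~110–125 phylotypes × 3
enzymes, 199–999 permutations for ANOSIM/AMOVA/P-test, and 10–100
simulation replicates for recovery rates — sizes chosen to exercise every
code path at full study structure while keeping a complete run fast on a
single CPU. Permutation p-values use the add-one convention, so the
smallest attainable p is 1/(n_perm + 1).

## Known limitations

- Greedy centroid clustering is one deterministic reading of
  "99% identity grouping"; assembly-style tools can merge chains of
  near-identical sequences differently, so absolute OTU counts on real
  data are tool-dependent.
- The variable-threshold procedure is a reconstruction of the published
  idea (smallest percentage decoupling richness from loading); the
  original tool's exact grid and test are not specified anywhere.
- Matching is study-wide, not per-sample; a phylotype can be "explained"
  by a fragment observed only in a different source.
- NRI/NTI null models beyond tip-shuffle (e.g. abundance-weighted or
  phylogeny-randomizing nulls) are not implemented.
- The log-linear classification of environmental-identity classes and any
  live BLAST/taxonomy assignment are out of scope by design; annotations
  are inputs.
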