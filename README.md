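# rootarch

Root-system architecture (RSA) phenotyping for 2D root-network scans,
built for screening large diversity panels — the reference design is
200 potato genotypes grown in flat rhizotrons under high (HP) and low
(LP) phosphorus with two replications per treatment.

The package covers the full analysis chain:

1. **Trait extraction** — 22 traits per plant from a binary
   white-on-black root mask plus dry weights: size (NeA, NeL, NeP,
   NeSA, NeV, ARW), extent (MaEA, MiEA, NeCA, NeD, NeW), distribution
   (MaNR, MeNR, NeB, NeLD, NeS, SRL), shape (EAR, NeWDR) and weight
   (SDW, RDW, SRR).  The skeleton (topology-preserving thinning)
   together with the Euclidean distance transform gives root length,
   local radius, tubular surface area and volume; the convex hull and
   second-moments ellipse describe extent; a horizontal line sweep
   counts roots per image row, with MaNR the 84th-percentile count
   (nearest rank) and MeNR the median.
2. **Statistics** — balanced three-way ANOVA (genotype G, environment
   E, replication R treated as a year-like factor, no residual
   stratum), method-of-moments variance components, and broad-sense
   heritability

   h² = σ²g / (σ²g + σ²ge/2 + σ²gr/2 + σ²ger/4),

   plus per-environment trait summaries and the Pearson correlation
   matrix of z-score standardized genotype means with significance
   stars.
3. **Classification** — per-environment z-scores, PCA (Dim1/Dim2
   biplot exports), hierarchical clustering of genotypes into k = 3
   rooting types labelled small/medium/large by their size-trait
   scores, the HP→LP 3×3 transition matrix, and Newick/tanglegram
   export of the paired dendrograms.
4. **Synthetic data** — a root-growth simulator (primary axes with
   Poisson-spawned laterals, tortuosity noise, gravitropic pull) with
   exact centerline ground truth, and an additive trait-table
   generator with known variance components and planted rooting types,
   so every stage can be validated against truth.

## Worked example

Run the whole pipeline on a simulated 10-genotype experiment (40
images: 2 treatments × 2 replications):

```sh
cat > run.yaml <<EOF
out_dir: demo/out
seed: 1
n_genotypes: 10
px_per_cm: 25.0
EOF
rootarch run --config run.yaml
```

which prints `pipeline ok; report at demo/out/report.json` and writes
`traits.csv`, `trait_table.csv`, `correlations.csv`, `labels.csv`,
PCA scores/loadings, `transitions.csv` and the two Newick dendrograms.
The trait table starts

```
trait,HP_mean,HP_sd,LP_mean,LP_sd,E,G,GxE,h2,...
ARW,0.081428,0.000962036,0.0812951,0.000798413,NS,***,NS,0.907544,...
EAR,0.805018,0.0937033,0.806701,0.106473,NS,NS,NS,0,...
```

— per-trait HP/LP means and s.d., significance stars for the
environment, genotype and G×E effects, and the heritability estimate
(ARW is highly repeatable across these synthetic replicates; EAR is
pure noise here, hence h² = 0).  The PCA variance file shows the
size-dominated first component (`HP,Dim1,77.7383` percent in this
small run), `labels.csv` assigns each genotype a rooting type per
treatment,

```
genotype,environment,cluster,size_label
G001,HP,1,small
G002,HP,2,medium
```

and `transition_summary.json` reports how many genotypes keep their
type from HP to LP (here `same_pct: 100.0` — the simulated types are
stable by construction).

Each stage is also a standalone subcommand (`rootarch simulate |
extract | stats | classify`) and a plain library call; see
`docs/methods.md` for the model details and conventions.

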