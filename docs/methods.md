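# Methods

## The screen model

A dual-guide construct carries two spacers (crRNAs) expressed from a U6
promoter (position 1, "left") and an H1 promoter (position 2, "right"),
each fused to its own tracrRNA scaffold. The simulator and the estimators
share one generative model for a construct's expected log2 fold-change
(gDNA vs pDNA):

    LFC(c) = eff_L · e(gene_L) + eff_R′ · e(gene_R) + eff_L · eff_R′ · i(pair)
    eff_R′ = eff_R · promoter_bias

where `e(g)` is the gene's fitness effect in LFC units (negative =
depleting), `i(a,b)` the genetic-interaction (synthetic-lethal) effect, and
`eff ∈ [0, 1]` the guide's knockout efficacy. The interaction term is
multiplicative in the two efficacies, so an inert guide nullifies both its
single-gene term and the interaction — matching the observation that a few
ineffective guides bifurcate double-knockout signal. The promoter bias is a
multiplicative efficacy factor on the H1 position (default 0.85 < 1: the
U6-driven guide cuts somewhat better).

### Counts

pDNA abundances are overdispersed: per-construct gamma weights with unit
mean and variance `pdna_abundance_dispersion` (default 0.1), then one
multinomial draw of `sequencing_depth × n_constructs` reads
(gamma-multinomial ≡ Dirichlet-multinomial; one tunable overdispersion
parameter; no noise model is prescribed by the screen design itself, so the
default is a deliberate, calibration-free choice). Each gDNA replicate is an
independent multinomial with proportions ∝ pDNA × 2^LFC at the same depth.
Replicates therefore differ by counting noise only.

### Recombination

Template recombination between the two homologous scaffold regions is
modeled at the molecule level: a binomial fraction `recombination_rate` of
each construct's pDNA molecules is marked recombined. A recombined molecule
behaves as if its position-2 guide were lost (fitness = left-guide-only
LFC; the deletion-type recombinant keeps its U6 cassette), and the reads it
emits carry the position-1 scaffold of a random other construct in position
2 while both crRNAs stay intact. Consequences that the pipeline measures:

- the read-level scaffold-mismatch fraction equals the simulated rate
  (binomial recovery, ±3 SE);
- crRNA-resolution counts mix intact and recombined molecules, diluting
  depletion — most strongly for strong effects and only in the H1 position;
- sgRNA-resolution counts (both scaffolds matching) recover the intact
  population at the price of discarding the mismatched reads.

A purely read-level swap (leaving counts untouched) could not reproduce the
second point; the molecule-level model is the minimal one in which
sgRNA-level mapping rescues depletion. Note that because recombination
shrinks essential *and* background scores roughly proportionally at the
crRNA level, NNMD — which normalizes by the null spread — cancels most of
the shrinkage; the rescue is therefore assessed on H1-position single-gene
scores, where the dilution is concentrated and the differential is robust.

### Reads

Read 1 covers `[0–8 nt stagger] + vector flank + crRNA_L + tracrRNA_L`;
read 2 is the reverse complement of `linker + crRNA_R + tracrRNA_R + flank`
(150 nt, no quality model). The vector flank, linker and scaffold sequences
shipped with the package are synthetic stand-ins (random, mutually
divergent); the real variant scaffolds are not distributed and can be
supplied as a `tracr_sequences` mapping. Mapping is anchor-based: the
constant flank is located by exact match over stagger offsets 0–8, the
spacer is read at a fixed offset (0 substitutions allowed by default), and
the following k nt (default 10) are compared to the construct's expected
scaffold prefix with ≤ 1 mismatch — the scaffold set is divergent enough
that one sequencing error cannot flip identity.

## Statistics

- **Normalization**: `log2((x + 1) / column_total × 10⁶)`. The pseudocount
  breaks exact scale equivariance; at screen depths the discrepancy is
  < 0.01 log2 units.
- **Compositional centering**: depletion of essential constructs inflates
  every other construct's relative abundance. `center_lfc` anchors each
  replicate on the median LFC of the neutral–neutral control constructs
  (true LFC 0). The synergy score is invariant to the shift (it cancels in
  `min(singles) − double`), so centering matters only for absolute
  gene-effect recovery and threshold metrics.
- **Synergy null**: a 1-D Gaussian mixture is fitted by EM to the synergy
  scores of non-synergistic pairs (the expression-silent pair set in real
  data; the planted null pairs in simulations), with k ∈ {1, 2, 3} chosen by
  BIC, 5 seeded restarts, tolerance 1e-8, max 500 iterations, and a 1e-6
  variance floor for degenerate input. p = Σ_j w_j · Φ̄((s − μ_j)/σ_j);
  BH step-up FDR. At least 20 null scores are required.
- **NNMD** uses the median/MAD form, `(median(ess) − median(non)) /
  (1.4826 · MAD(non))` (the name says "median"); a mean/SD variant is
  available behind `robust=False`. More negative = better separation.
- **AUC** treats lower (more depleted) scores as the positive class and is
  the tie-corrected rank statistic.
- **Two-class pair tests**: for pair (A, B), dependency of A is compared
  between B-LOF lines and the rest — one-sided KS (LOF group stochastically
  greater) and one-sided Fisher on dependency ≥ 0.5 — in both directions,
  each family BH-adjusted across all tested directions; a direction needs
  ≥ 3 LOF lines. Significance percentile of a p-value is the fraction of
  tested directions with p at least as large (so smaller p → percentile
  nearer 1), "top 10 %" = mean percentile ≥ 0.9. A pair is selected when
  either direction passes min(FDR) < 0.05 and the percentile rule.
  Threshold boundaries follow their sources exactly: the dependency-fraction
  thresholds are strict (> 0.8 in > 90 % etc.), the copy-number rule is
  inclusive (≥ 2 SD below the mean), the expression rule is inclusive
  (≥ 90 % of lines).
- **Guide agreement**: features per guide pair over shared cell lines —
  Pearson r, Spearman r, mean |difference|, SD ratio (min/max), overlap of
  the most-depleted deciles. A 200-tree random forest
  (`min_samples_leaf=20`) is trained on distinct same-gene vs distinct
  random-gene pairs (defaults 5000/5000, capped for small inputs). Two
  deliberate choices: pairs are sampled *without* duplication, because a
  duplicated pair leaks identical feature vectors across the holdout split
  and inflates the AUC; and leaves are regularized, because within-gene
  pairs are later scored with the same model and fully-grown trees would
  replay their own training labels. The feature set and hyperparameters are
  this package's own — a re-implementation in the spirit of the published
  approach, which did not specify them. Per-gene groups are connected
  components of the score > 0.7 graph with ≥ 3 members (a "group" is not
  otherwise defined; components are deterministic and linear-time, a clique
  rule would be stricter).

## Simulator defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| guides_per_gene | 6 | study design (3/3 positional split → 18 per pair) |
| n_replicates | 3 | three biological replicates |
| essential_effect | −2.0 LFC | typical pan-essential depletion |
| sl_interaction_effect | −1.5 LFC | strong synthetic-lethal interaction |
| guide_efficacy | Beta(5, 2) | mean ≈ 0.71, realistic efficacy spread |
| promoter_bias | 0.85 | U6 > H1, modest |
| pdna_abundance_dispersion | 0.1 | plasmid-pool unevenness |
| sequencing_depth | 1000 reads/construct | ~500–1000× coverage practice |
| background_effect_sd | 0 | exact null by default; set ≈ 0.15 for the biological spread nonessential genes show in real screens |

All randomness flows from one integer seed through counter-based
`SeedSequence` splitting (separate streams for library, counts, reads,
cohort, guide matrix), so each stage is independently reproducible.

The generator does **not** emulate: PCR amplification bias, sequencing
errors, MOI/infection statistics, copy-number-driven cutting toxicity,
cell-line-specific Cas activity, or guide off-target fitness effects.
Passing recovery tests therefore demonstrates estimator correctness under
the stated generative model, not robustness to those real-data artifacts.

The DepMap-like cohort plants synthetic-lethal pairs (partner LOF lines ~12 %
of the cohort, dependency Beta(12, 2) there vs Beta(1, 12) background),
pan-essential genes (dependency Beta(30, 1)), silenced nonessential genes,
and expression-silent pairs; copy-number background is N(0, 0.2) with −1.5
losses and truncating mutations driving LOF. The guide-LFC matrix gives each
gene a shared N(0, 1) cell-line profile observed by its guides with
N(0, 0.25) noise; inert guides are pure noise.

## Problem sizes

Test and analysis runs use desk-scale screens: tens of genes, up to ~50
pairs, depth 1000–2000, 10⁵ read pairs for rate estimation, a 200-line
cohort, 20-seed calibration batteries. These sizes give the estimators
standard errors comfortably inside the asserted tolerances while keeping
the full suite under a minute of simulation time.

## Known limitations

- The full Bayesian guide-level model of the GEMINI package is intentionally
  not re-implemented; effects are replicate-pooled means of construct LFCs,
  and the synergy/FDR machinery follows the mean-based description. Scores
  will differ from GEMINI's latent-efficacy estimates on real data.
- Recombination is simulated and detected only at the tracrRNA junction;
  crRNA-pair scrambling (chimeras that swap spacers) is out of scope.
- The exact tracrRNA variant sequences, the stagger-primer table and the
  real vector context are not distributed; synthetic stand-ins preserve the
  structure (unique anchors, divergent scaffold prefixes) but not the
  sequences.
- Whether single-gene guides should occupy both positions (12 constructs
  per gene, the default here) or be split 3/3 (6 per gene) is a design
  choice; `design_single_constructs(both_positions=False)` gives the
  latter.
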