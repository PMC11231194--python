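# Methods

## Problem setting

`ctpflow` implements the computational core of a systems-pharmacology screen
for multi-herb prescriptions: given a compound library with herb membership
and predicted ADMET/physicochemical properties, predicted compound–target
interactions, a disease (pathogenic) gene list, protein–protein interactions
(PPIs), pathway/GO annotations and a case/control expression matrix, identify
a small subset of compounds that accounts for most of the prescription's
predicted interaction intensity on disease genes, and rank the pathways that
intensity concentrates on.

## Compound screening

A compound passes iff it fulfils all nine rules (inclusive comparisons):
MW ≤ 500 Da, nHD ≤ 5, nHA ≤ 10, logP ≤ 5, nRot ≤ 10 — the Lipinski-style
drug-likeness block — plus predicted oral bioavailability OB ≥ 30 %, Caco-2
permeability ≥ 0.4 (applied to the supplied numeric column as-is, whatever
scale the upstream predictor used), TPSA ≤ 60 Å², and no predicted
hepatotoxicity. A missing property fails its rule with a `missing:<field>`
violation: a criterion cannot be *fulfilled* when the value is unknown.
Rules are data and can be overridden per run; the defaults are pinned.

## C-T-P network

The tripartite network has compound nodes, and a protein layer that is the
union of predicted targets T (from compound–target edges of pass-set
compounds; the union over prediction sources, deduplicated) and pathogenic
genes P. ECPs (essential common proteins) are T ∩ P. PPI edges are undirected,
unweighted, deduplicated as unordered pairs, self-loops dropped, and retained
only when **both** endpoints are in the protein layer — the network contains
no other node classes, so edges leaving the layer carry no information for
the downstream flow. Isolated pathogenic genes are retained as nodes.

## Multi-objective optimization

Each target gene g gets three objectives, each min–max normalized over the
target set (a constant objective maps to zeros, with a warning):

- **o_compound** — number of incident compound–target edges, or the sum of
  prediction scores when edges carry scores;
- **o_pathogenic** — number of PPI neighbors that are pathogenic genes, plus
  1 if g is itself an ECP;
- **o_dysreg** — |log2 fold change| from the DE table (0 when absent).

The score s(g) ∈ [0,1] is the weighted mean (default equal weights). This is a
deliberately transparent scalarization of the three stated optimization goals
(compound association, disease-gene association, dysregulation); it does not
claim fidelity to any particular published multi-objective optimizer.

Pruning keeps targets with s ≥ the (1 − keep_quantile) quantile of scores
(linear-interpolation quantile; ties at the boundary retained; default
keep_quantile = 0.5). All compounds and all pathogenic genes stay;
compound–target edges survive iff their target survives; PPI edges survive
iff both endpoints remain nodes and at least one endpoint is a retained
target or an ECP. keep_quantile = 1 is the identity apart from attaching
scores. Retention is monotone in keep_quantile by construction.

**Baselines.** Degree (PPI degree + compound–target degree), closeness and
betweenness centrality score targets instead of the MOO score, with the same
normalization and retention rule. Path-based centralities are computed on the
protein–protein subgraph only, because compound nodes would distort shortest
paths among proteins; closeness uses the component-wise convention (isolated
nodes score 0).

**Model comparison** reports five metrics per model: ECP coverage of the
retained target set; overlap of the model's top-100 enriched pathways and
top-1000 enriched GO biological processes with reference lists enriched from
the ECP set; average regulating intensity — the mean Pearson correlation over
expression profiles of gene pairs joined by a *retained PPI edge* (pairs, not
all retained genes; pairs lacking expression are skipped and counted; the
metric is unavailable with fewer than 3 samples); and cumulative differential
expression — Σ|logFC| over retained ECPs. Correlations use all samples, cases
and controls together.

## Interaction-intensity flow

With s the per-target scores of the optimized network:

- gene: Intensity_k = s(k) if k ∈ T ∩ P; otherwise the mean of s over the
  retained targets sharing a PPI edge with k (0 when there are none);
- compound: C_i = direct pathogenic targets of i plus pathogenic genes one
  PPI hop from a target of i; Intensity_i = Σ_{k∈C_i} Intensity_k;
- combination: the union of the members' C_i, each gene counted once — this
  makes the objective monotone submodular and keeps the all-compound total
  equal to "the intensity of all compounds", so a 90 % threshold is
  well-defined;
- pathway: Intensity_p = Σ_{k∈p∩P} Intensity_k / n_k, where n_k is the number
  of pathways gene k belongs to, so Σ_p Intensity_p conserves the total
  intensity of pathway-annotated pathogenic genes (checked to 1e-9).

All flows scale linearly in s: multiplying scores by c > 0 scales every
intensity by c and changes no ranking and no selected combination.

**Combination selection.** Scanning sizes m = 1, 2, …, the optimal
combination per size is the one with maximal union intensity; the result is
the first size whose optimum reaches threshold × total (inclusive; default
0.9). The exact solver enumerates all combinations per size (guarded by
`exact_limit`, default 15 compounds) and breaks ties lexicographically on
sorted member ids — needed for determinism, since distinct subsets can tie
exactly. The greedy solver adds the compound with maximal marginal union gain
(ties: larger single-compound intensity, then smaller id); greedy carries the
standard (1 − 1/e) maximum-coverage guarantee and is oracle-tested against
exhaustive enumeration on instances of ≤ 12 compounds.

## Enrichment and differential expression

Over-representation uses the upper-tail hypergeometric probability
P[X ≥ k] (the observed overlap included) with BH FDR control across terms and
significance at FDR ≤ 0.05. The universe defaults to all genes annotated in
the collection (overridable); the ≥ 10 minimum term size counts **in-universe**
members. Top-N lists keep ties at the cut (the list may exceed N, logged).

`simple_de` is a plain two-group summary: logFC = mean(case) − mean(control)
on log2-scale values, Welch t-test, BH adjustment, significance at
|logFC| > 1 and FDR < 0.05. Genes with zero variance in both groups get
p = 1. This deliberately replaces moderated empirical-Bayes statistics with
an unmoderated test; at the generator's default depth (10 vs 10 samples,
σ = 0.5) moderation changes little, and precomputed DE tables from dedicated
tools are accepted everywhere a DE table is consumed.

## Synthetic data

The generator emulates the study's input shapes at desk scale with planted
truth; all randomness flows from one integer seed and the same seed gives a
byte-identical bundle.

- **Compounds**: 8 herbs × 25 compounds; 15 % assigned to ≥ 2 herbs; pass
  labels drawn first at fraction 0.22 (comparable to observed pass rates of
  rule-based ADMET screens of herbal libraries), then properties sampled
  inside or outside the rule region conditional on the label, so screening
  recovery is exact rather than probabilistic.
- **Genes**: 150 targets, 200 pathogenic genes, 40 of them ECPs (a designated
  subset of targets). Every target is seeded with at least one
  compound–target edge, so the ECP set computed from the files equals the
  planted set; passers then draw 3–10 targets each, choosing an ECP with
  probability 0.6 (the planted high-signal structure).
- **PPI**: Erdős–Rényi background (p = 0.01) plus 4 planted links from each
  ECP to pathogenic genes, plus 5 decoy hub targets with ~30 links to
  non-disease targets. The hubs give centrality baselines something to rank
  highly that carries no disease signal — the property the multi-objective
  model is supposed to be robust to.
- **Expression**: log2-scale Gaussian model, baseline U(4, 10), σ = 0.5,
  10 case + 10 control samples; signed effects of magnitude 2.0 planted on
  40 % of ECPs.
- **Gene sets**: 40 pathways (10–30 genes) and 120 GO-BP-like sets (10–25),
  ~30 % of them biased toward disease genes.

What the generator does **not** emulate: real ADMET predictor error
structure, correlated chemical properties, scale-free PPI topology, gene–gene
expression correlation beyond planted mean shifts, and annotation bias.
Passing tests therefore demonstrate correctness of the algorithms under the
planted model, not biological performance on real databases.

The fixed worked toy (3 compounds A/B/C, 3 ECPs G1–G3 with planted scores
0.5/0.5/0.4) pins the intensity arithmetic: intensities A = 1.0, B = 0.9,
C = 0.4, union total 1.4, minimal 90 % combination {A, B}. Its input files
also include a hand-set DE table under which the pipeline's own computed
scores select {A, B} end-to-end.

## Numerical choices and degenerate inputs

- Quantile thresholding via numpy's interpolated quantile; ties retained.
- Min–max normalization maps constant vectors to zeros (warned) to avoid 0/0.
- Threshold qualification uses ≥ with a 1e-12 slack against float noise.
- Empty enrichment tables, compounds with empty reachable sets, isolated
  pathogenic genes and score-free edges are all defined (zero / skipped with
  a log line), not errors; empty compound or pathogenic inputs are fatal.
- Reports are JSON with sorted keys and no timestamps or absolute paths, so
  fixed-seed runs are byte-identical.

## Problem sizes

Defaults were chosen so a full synthetic run takes well under a second and
the complete benchmark (20 replicates × 4 models) a few seconds on one CPU;
they are configuration, not limits — every size is a `GeneratorConfig` field.

## Known limitations

- The scalarized multi-objective model is one documented choice among many;
  an optional Pareto-rank mode was considered and not implemented because the
  equal-weight mean already satisfies every stated behavioural property and
  keeps the score interpretable. Weights are configurable.
- The one-hop definition of a compound's reachable pathogenic set keeps the
  flow local; longer-range propagation (diffusion kernels) is out of scope.
- `simple_de` is not a replacement for moderated DE statistics on real
  few-sample microarray data; supply a precomputed DE table for such inputs.
- SMILES strings are carried but not validated or used.
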