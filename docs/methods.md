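# Methods

## Constraint-based model

A metabolic network is a stoichiometric matrix `S` (metabolites × reactions)
with per-reaction flux bounds `l ≤ v ≤ u` (arbitrary flux units; defaults
±1000, or 0..1000 for irreversible reactions). All analyses work on the
steady-state polytope `{v : S v = 0, l ≤ v ≤ u}`. No biomass objective is
assumed anywhere: for mammalian multi-tissue systems a single cellular
objective is not identifiable, so flux variability analysis (FVA) is defined
as the plain per-reaction minimum and maximum over the polytope, with no
optimality constraint. Linear programs are solved with HiGHS
(`scipy.optimize.linprog`); infeasibility and unboundedness are reported as
statuses, not exceptions, because the extraction loop routinely probes
infeasible configurations.

Compartments are encoded as bracketed metabolite suffixes (`[c]` cytosol,
`[e]` extracellular). An *exchange* reaction touches exactly one
extracellular metabolite and crosses the system boundary; written in sink
orientation (`1 A[e] ->`) positive flux is secretion, so an upward shift in
its flux interval reads as a concentration increase in the blood
compartment. Supplies (diet) are written in source orientation
(`-> 1 A[e]`). A *transport* reaction moves a species between a tissue
cytosol and the shared extracellular compartment. Tissue tags are metadata
(reaction prefix, metabolite suffix) applied only at serialization, so
multi-tissue expansion never depends on parsing IDs.

Dead-end pruning removes metabolites that cannot be both produced and
consumed (a reversible reaction counts as both producer and consumer of
everything it touches) together with their reactions, iterating to a fixed
point; the operation is idempotent and its output is flux-consistent in the
usual sense once combined with blocked-reaction removal.

## MCL extraction

Inputs: a flux-consistent network and a disjoint partition of its reactions
into high (`C_h`), medium (`C_m`) and low (`C_x`) confidence tiers, with
`C_x` defaulting to the complement. The target is the subnetwork `R_p`
containing all of `C_h` that maximizes `|R_p ∩ C_m| − w·|R_p ∩ C_x|`. The
penalty weight `w` defaults to 0.5, which balances parsimony (dropping
uncertain reactions) against medium-tier coverage; it is exposed as a
parameter.

The search samples the polytope instead of enumerating elementary flux
modes: each column of the flux-distribution matrix is the Boolean activity
pattern (|v| > 1e−6) of one LP solution whose objective is a unit-weight sum
of `k` reactions drawn uniformly without replacement from `C_h ∪ C_m`
(`k = 3` by default; low-confidence reactions never enter an objective).
Solutions are post-processed to parsimonious flux vectors (a second LP
minimizing total |v| at the fixed objective value). This is a deliberate
design choice: raw simplex vertices routinely carry full-bound flux through
reactions irrelevant to the objective, which would make nearly every column
activate entire low-tier pathways; parsimonious patterns hug elementary
modes, which is the rationale for sampling LP solutions in the first place.
Infeasible or degenerate solves yield all-zero columns, which are retained
(score 0, never selected) and counted.

The greedy pass scores every column (`#active medium − w·#active low`),
then: (1) while uncovered high-confidence reactions remain, adds the
best-scoring column activating at least one of them (ties break on the
lowest column index, so runs are reproducible under a fixed seed); (2) keeps
adding the best-scoring column while the best score is positive. Added
reactions' rows are zeroed and scores recomputed after every addition. If no
sampled column activates some high-confidence reaction, a targeted LP
maximizing (and, for reversible reactions, minimizing) that reaction's flux
supplies the missing pattern; only if that also fails is coverage reported
as impossible, listing the uncovered IDs.

The outer loop rebuilds the matrix on the current partial model and re-runs
the pass from scratch, stopping when the reaction count repeats
(`max_outer_iterations` 20 by default). Production sampling depth is 10,000
columns per iteration; a few hundred suffice for the toy networks used in
tests, where the result provably equals the brute-force optimum over all
flux-consistent supersets of `C_h` (enumeration oracle in
`mclx.reference`).

## Gene deletion analysis

A disorder is a set of causal genes. Affected reactions are those whose GPR
rule evaluates false with those genes absent and all others present — full
Boolean evaluation, so an OR-isozyme rescues its reaction. The reference
model forces the affected reactions on (lower bound 1, unconditionally
overriding a negative bound) so the healthy model must use them; the disease
model removes them. FVA over the exchange reactions gives two bounds tables,
compared by the normalized delta

    delta_i = ((diseaseMin_i + diseaseMax_i) − (refMin_i + refMax_i))
              / max(|mean(refMin_i, refMax_i, diseaseMin_i, diseaseMax_i)|, 1e−6)

(the denominator floor guards identical all-zero intervals). Calls are
`increased` above +ε, `decreased` below −ε, else `unchanged`; raising ε can
only move calls toward unchanged (nesting), which is what makes the ε-swept
ROC well defined. Disorders whose forced reference is infeasible are
reported as not simulable and excluded from scoring. The 17 amino-acid
disorder gene sets used for this validation ship as a packaged table
(without phenotype arrows, which are user-supplied).

## Fold-change analysis

The pipeline starts from a significance-filtered differential-expression
table (p < 0.05, fold change > 1.5; the filter is re-applied on read).
Multiple probe records for one gene are collapsed by majority vote (tie →
unchanged); distinct genes combine through GPR logic with AND taking the
most restrictive branch (a complex is limited by its scarcest subunit) and
OR the least restrictive (an isozyme rescues).

Bounds protocol: status-affected reactions are first set to bound magnitude
100 — one tenth of normal — so that the subsequent doubling of upregulated
bounds can actually relax a constraint; unaffected reactions keep ±1000;
exchange reactions are pinned to [1, 1000] in their written direction,
forcing every boundary flux on. The control model is FVA'd, then upregulated
bounds are doubled and downregulated bounds halved and FVA repeated; deltas
and calls are computed as above. The forced exchange bound follows the
protocol verbatim even though it can make some networks infeasible; such
runs report the binding exchange, and `--exchange-lb 0` relaxes it for
exploratory work.

Concentration readout uses either exchanges directly or, preferably, the
per-amino-acid sum of deltas over all of its cytosol↔extracellular
transporters across tissues (a parallel unaffected route can mask the effect
on a single exchange). Sign interpretation depends on the transporter's
written orientation: for an uptake-oriented transporter a negative summed
delta means reduced clearance from blood — extracellular accumulation. The
packaged down-catabolism fixture writes its transporter in uptake
orientation for exactly this reading.

Subsystem summaries code calls as down = −1, unchanged = 0, up = +1 and
compare each subsystem against a same-size sample drawn uniformly from
{−1, 0, +1} (a random selector picks each class a third of the time) with a
Welch two-sample t statistic, drawn once per subsystem from a global seed.
Sorting by t ranks coherently downregulated subsystems first and
automatically discounts tiny subsystems (an all-down pair is matched by
chance 1/9 of the time and scores weakly). Subsystems with fewer than two
reactions have no t and are reported as missing.

A structural asymmetry follows from steady state: a downregulated step
throttles every reaction in series with it, while an upregulated step cannot
force flux through unchanged neighbours — so balanced gene perturbations
yield more down calls than up calls. This is asserted statistically over a
family of random toy networks.

## Evaluation

Direction tables are scored with: TP = changed call matching a changed
truth; FP = changed call when truth is unchanged *or opposite* (a
direction mismatch is a false positive, not a false negative); TN = both
unchanged; FN = unchanged call against a changed truth. This convention
reproduces all sixteen confusion counts of the packaged validation table
exactly. Metrics (precision, recall = TPR, TNR, FPR, accuracy) are kept at
full precision internally and rounded half-away-from-zero to two decimals
only for presentation; 0/0 is reported as undefined, never as 0.

ROC curves sweep ε over 0 plus 200 log-spaced values up to 1000; AUC is the
trapezoid over FPR-sorted points with anchors (0,0) and (1,1). Two scoring
modes exist. The *directional* mode applies the convention above; because a
random direction is usually wrong, its chance level is ≈0.25, not 0.5 —
the same effect that places a random selector's AUC below 0.5 in this kind
of validation. The *magnitude* mode asks the standard binary question (does
|delta| separate changed from unchanged items) and has the textbook chance
level of 0.5; it is used for calibration checks (perfect separator → 1.0,
independent uniform deltas → ≈0.5).

## Synthetic fixtures

Toy networks are parallel linear pathways from one shared extracellular
substrate to one shared product, one gene per internal reaction, with the
two boundary exchanges always high-confidence; tier plans per pathway make
the extraction optimum computable by enumeration. The planted
down-catabolism fixture is a single uptake-and-degrade route (6-reaction
catabolic chain, all genes planted down). Synthetic expression tables give
planted genes |log2FC| ≥ log2 1.5 at p < 0.05 and noise genes sub-threshold
records. These fixtures emulate the *structure* of real inputs — not
microarray intensity distributions, genome-scale redundancy, isoform-rich
GPRs, or thermodynamic constraints — so passing tests demonstrate
correctness of the machinery, not predictive performance on real tissue
data; the genome-scale figures additionally require the full human
reconstruction, curated tier lists and the deposited expression data, which
are external inputs.

## Numerical choices

- LP feasibility/activity tolerance: 1e−6 flux units (conventional).
- Delta denominator floor: 1e−6.
- Column tie-break: lowest index; all randomness flows from explicit
  `numpy` generators seeded per run, so identical configuration + seed
  gives identical primary outputs.
- Internal (type III) loops are tolerated, not eliminated; FVA reports the
  full ±bound interval for them.
- Problem sizes in tests and the acceptance script (≤12-reaction toys,
  200-column sampling, 20 extraction replicates, 10 vertex-enumeration
  networks, 1000-item chance tables) are chosen so the brute-force oracles
  remain exact and runs finish in seconds.

## Known limitations

- The extraction is stochastic-greedy: optimality is proven only against
  enumeration on small instances; at genome scale replicate runs agree in
  size but not necessarily reaction-for-reaction.
- The exchange-forcing protocols (deletion lower bound 1, fold-change
  exchange bounds [1, 1000]) encode the published procedure and can be
  infeasible on networks not written with them in mind; both report rather
  than silently relax.
- Direction calls are qualitative; no kinetic or thermodynamic information
  enters the bounds beyond reversibility.
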