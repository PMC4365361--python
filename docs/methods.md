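# Methods

## Encoding incomplete attribute values

Every attribute of the six-column schizophrenia record owns a closed,
non-degenerate domain [y_min, y_max]. An observation is one of four
shapes: a point, an interval [lo, hi], a finite candidate (abducible) set,
or the unknown token ⊥. Encoding proceeds in three steps per attribute:
widen to a continuous interval (point x → [x, x]; ⊥ → the full domain; a
finite set → its hull, its cardinality being relevant only to the QoI
calculus), min-max normalize against the domain, and score the Degree of
Confidence

    DoC = sqrt(1 - dl^2),

with dl the normalized width. The square-root form is the geometric
construction on the unit circle (the height over a chord of length dl) and
is the form every worked reference value satisfies; we adopt it as the
single DoC definition. The record-level DoC is the arithmetic mean of the
six attribute DoCs — again the aggregation that reproduces all reference
records. The alternative composition through the weighted score V (see
below) does not reproduce them and is therefore provided as a separate
function, not wired into the pipeline.

Out-of-domain observations raise an error naming the attribute; clamping
would silently hide data-entry faults. Degenerate (zero-width) domains are
rejected rather than mapped to DoC 1, as no clinical attribute range is a
single point.

### Reporting conventions

Core computations keep full precision. For display and for matching
published values, bounds and aggregates are rounded half-up at 2 decimals
and attribute DoCs at 3. Two published conventions are reproduced
explicitly rather than absorbed into the core: the age/sex attribute DoC is
printed as computed on the 2-dp-rounded normalized bounds
(`doc_from_rounded_bounds`: [0.6667, 1] → [0.67, 1.00] → 0.944, where full
precision gives 0.943), and one toy value is truncated rather than rounded
(0.91651 → 0.916; `truncate_report`). Printed-value comparisons use
|Δ| ≤ 1e-3 per attribute and 5e-3 on 2-dp aggregates to accommodate the
mixed rounding/truncation.

## Quality of Information

Per argument: known → 1; unknown → 0 (the limit of 1/N over an unbounded
admissible set); a finite abducible set of Card candidates → 1/Card when
the candidates are mutually exclusive, and 1/(2^Card − 1) — one over the
number of non-empty subsets — when they are not. The weighted score
V = Σ w_k·QoI_k / n uses non-negative weights validated to sum to 1
(default: equal weights; no reference weight assignment exists). Record
annotations carry QoI 1 by default, the convention the worked records
follow even when arguments are unknown; `min` and `mean` aggregation
policies over per-attribute QoIs are available. The QoI annotations 0.5
and 0.6 attached to the two toy records in the source material are not
derivable from the stated calculus; they are left unexplained rather than
reverse-engineered.

## Clinical schema

The age/sex predisposition table (annual incidence per 1000, seven age
bands × two sexes) and the genetic predisposition table (15
closest-relative categories, 0.9% for the general population to 91.5% for
a co-resident monozygotic twin) ship as CSV files under `schizodoc/data`.
Age bands are inclusive integer-year ranges; the table leaves age 65
unassigned between "55–64" and ">65", and we place it in the open-ended
band so coverage is gap-free. The incidence interval is consumed as
printed, without rescaling; consequently the age/sex attribute is
interval-valued even for a fully specified patient and its DoC is below 1
by construction. The genetic attribute uses the single closest
(highest-risk) relative; combining multiple relatives is out of scope.

Lucidity (drugs × alcohol × somnolence × consciousness, range [0,2]) and
differential (neurological × infectious × toxic/metabolic, range [0,1])
are endpoint interval products — valid because all factors are
non-negative — and Ks1/Ks2 are componentwise interval sums. Unknown
sub-cells are widened to their domains first, so partial knowledge
degrades the derived attribute instead of destroying it; a derived hull
that covers the whole domain is canonicalized to ⊥, which is what makes a
(1, 1, ⊥) differential exactly equivalent to an unknown one.

## Synthetic populations

The generator emulates a psychiatric case database that does not publicly
exist. Each case draws a complete latent record: age uniform on 12–69, sex
balanced, relative category mostly `general_population` (70%, the rest
uniform), lucidity/differential factors benign with probability 0.98
(consciousness: waking 0.90 / obnubilation 0.09 / torpor 0.01) so the
diagnosis-voiding rule is exercised by roughly one case in eight, and
symptom grades from a 50/50 mixture of a healthy and an affected
categorical profile. The planted risk is

    risk = logistic(6·(Ks1/11) + 1.5·(Ks2/4) + (g/91.5) + 0.5·(as_mid/0.18) − 3)

— coefficients chosen once so that first-order symptoms dominate
second-order ones (6 vs 1.5 on unit scales), predispositions act as mild
priors, the all-zero profile scores below 0.1, the maximal profile above
0.9, and the default mixture yields 40–55% positive labels. A zero
lucidity or differential product returns the indeterminate sentinel
instead of a risk, and such cases are excluded from training by default
(optionally kept as negatives). Labels (risk ≥ 0.5, optional flip noise)
are computed on the latent record *before* masking, so degradation changes
information content but never ground truth. Masking replaces each of the
15 sub-cells independently: unknown with probability `missing_rate`,
otherwise a blurred interval (± a quarter of the domain width, clipped)
with probability `interval_rate`; the categorical relation can only go
missing. The per-case random-draw count is constant, so populations with
identical seeds share latent records across degradation settings.

What the generator does **not** emulate: realistic prevalence, symptom
correlations within patients, longitudinal (6-month) trajectories, or
informative missingness (cells go missing independently of their values).
Classifier results on these populations therefore demonstrate that the
encoding preserves a recoverable signal and that the confidence output
tracks information content — not clinical performance on real records.

## The screener

Topology 18–8–2, logistic activations throughout, one hidden layer — the
smallest shape that recovers the planted rule reliably. The 18 inputs
(normalized lo, hi, DoC per attribute) already lie in [0,1]; no further
standardization. The class output trains with binary cross-entropy; the
confidence output, whose reference target is undefined, trains with
squared error against the input record's clause DoC — an explicit design
choice isolated behind the `confidences` argument of `train`. Optimization
is full-batch Adam (default learning rate 0.02, at most 800 epochs) with
early stopping on a seeded 10% validation split (patience 50) and
restoration of the best weights. Recorded loss checkpoints store the best
training loss reached so far, hence are non-increasing by construction.
All randomness derives from the config seed; identical data and config
give bit-identical weights. Models serialize to one JSON file with their
config, seed and a SHA-256 of the training arrays.

Evaluation sizes are deliberately desk-scale: populations of ~2500 cases
(420 per missing rate 0–0.5), 500 held out. On those, the screener reaches
held-out accuracy ≥ 0.9, a permuted-label control falls at chance
(0.5 ± 0.05), and predicted confidence correlates with the true record DoC
at Spearman ≥ 0.7; an off-the-shelf logistic regression on the same
features serves as an independent baseline cross-check. The published
single-patient network output (a detection at confidence 0.94) depended on
an unavailable training database and is a non-goal.

## Numerical and degenerate-input choices

Normalization tolerates round-off at the unit boundaries by 1e-12 and then
clips. `aggregate_doc` rejects empty lists; `train` rejects single-class
labels and non-finite features; empty CSV cells are an error (the unknown
token is an explicit `?`), interval cells use `lo..hi` to avoid locale
ambiguity. Record batches collect per-record failures with identifiers
instead of aborting on the first. The brute-force clause-DoC oracle in the
test suite recomputes every encoding step inline and agrees with the
pipeline to 1e-12 on 1000 random clauses.

## Known limitations

- The QoI calculus and the DoC pipeline are deliberately decoupled; record
  QoI defaults to the constant 1 annotation and carries no classifier
  weight.
- The second reference patient's single present second-order symptom is
  not identified in the source; the packaged fixture assigns perplexity,
  which is DoC-equivalent to any other choice.
- Interval blurring in the generator is symmetric and value-independent;
  real interval observations are usually asymmetric around the truth.
- The confidence output is only as meaningful as its clause-DoC target;
  it measures input completeness, not model calibration.
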