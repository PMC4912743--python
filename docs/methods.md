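# Methods

## Overview of the procedure

`prefscan` treats each protein site independently.  The 20 amino acid
preference values at a site are placed on a "higher = more favored" response
scale (direct preferences pass through; ΔΔG-style input is negated), then
regressed by ordinary least squares on each amino acid descriptor scale in
the selected sets.  A fit is retained when its Bonferroni-adjusted p-value
is at or below the family-wise cutoff `alpha` (default 0.05) and it passes
the optional `|r| ≥ r_min` and `RMSE ≤ rmse_max` limits (disabled by
default).  The best fit per site is chosen by scanning retained fits in
catalog order and replacing the incumbent only when a challenger's RMSE
decrease is significant by an F-test; unexplained sites are partitioned by
the tolerance metric k*.

Each step is a deliberate least-assumptions choice: OLS with 20 points per
fit, no cross-site pooling, no multivariate models, and explicitly no
treatment of intragenic epistasis or coevolution between sites — a site's
fit reflects only its own marginal amino acid distribution.

## The descriptor catalog

Thirty scales in four sets, scanned in order Set 1 → Set 4:

* **Set 1** (8): volume, log(solubility), hydrophobicity, isoelectric
  point, P(helix), steric hindrance, P(sheet), flexibility.
* **Set 2** (2): in vivo decay time, cost for synthesis.
* **Set 3** (16): arithmetic composites of Set-1 scales (e.g.
  Volume/P(helix)), derived elementwise at load time from whatever Set-1
  values are in force — built-in or user-supplied.
* **Set 4** (4): discrete side-chain composition counts (O, N, S atoms;
  H-bond donors + acceptors).

The shipped numeric values are standard published scales, each carrying a
provenance string: Zamyatnin residue volumes; CRC-handbook water
solubilities (g/100 g at 25 °C, log10-transformed); the Fauchère–Pliska
octanol/water π scale; free-amino-acid isoelectric points; Chou–Fasman
helix and sheet propensities; the Charton side-chain steric parameter;
Bhaskaran–Ponnuswamy B-factor-derived flexibilities; N-end-rule half-lives
in yeast (minutes); Akashi–Gojobori biosynthetic costs in high-energy
phosphate bonds.  Because the retained/rejected decision depends on the fit
statistics r and p, which are invariant to affine rescaling of a
descriptor, scales are used raw — no centering or standardisation — and
only the slope's units depend on the scale chosen.  Any scale can be
replaced through a custom tab-delimited descriptor file; a custom scale
that puts a zero in a composite's denominator is rejected rather than
propagated as infinity.

H-bond donor/acceptor counts follow a fixed convention: side-chain heavy
atoms only (backbone excluded), each atom counted once per role it can
play, Asp/Glu/Lys/Arg in their physiological charged forms, His neutral.

Set-3 composites are computed from the raw (not normalised) Set-1 scales.
Since every composite is a ratio, product or sum of two scales, this choice
affects only the composite's units, not which sites it explains.

## Alignment conversion and conventions

A gapped FASTA alignment plus a query identifier is converted to a ΔΔG
table per non-gap query position.  Conventions, each of which was a genuine
design choice:

* **Pseudocounts** — add-one (Laplace) per amino acid per column by
  default, exposed as a parameter.  This is the simplest standard smoothing
  and guarantees finite ΔΔG even when an amino acid (including the
  reference one) is absent from the column.
* **Query counting** — column counts are taken over the homolog rows only;
  the query row defines the reference amino acid at each position but is
  not itself counted as an observation.  The query is the coordinate
  system, not a sample: counting it would bias every column toward its own
  residue by exactly one count regardless of alignment depth.  Under this
  convention a column of N homologs all carrying the reference residue
  gives ΔΔG = log10(N + 1) for every substitution with add-one
  pseudocounts (N = 9 → 1.0), a closed form the tests pin down.
* **Coordinates** — residues are numbered by 1-based ungapped query
  position; a user offset maps to author/PDB numbering.  No automatic
  alignment of the table to the structure is attempted: residue matching
  for structure outputs is exact-number plus optional offset, kept simple
  and explicit.
* **Non-canonical letters** (B, Z, X, U, O) and gaps are excluded from
  counts; per-column excluded tallies are kept.  A column where every
  homolog is gapped is still emitted — the pseudocounts make it uniform,
  hence k* = 20 — but flagged low-coverage.

## The tolerance metric

k* = 2^H, with H the Shannon entropy (bits) of the site's amino acid
frequencies: the perplexity, or effective number of amino acids.  For ΔΔG
input the frequencies are recovered as P(i) = 10^(−ΔΔG(i)) (so the
reference amino acid has P = 1) and normalised; direct preferences are
normalised as given and must be non-negative.  The metric spans exactly
[1, 20]: 1 for a one-hot site, 20 for a uniform one, 2 for two amino acids
at 0.5.  Zero-frequency terms contribute nothing.  The positive exponent is
what reproduces these endpoints; user-provided k* columns are taken at face
value and never recomputed.

Unexplained sites with k* < `k_low` (default 4) are flagged low-tolerance
(active-site-like conservation) and with k* > `k_high` (default 16)
high-tolerance; both thresholds are configurable.

## Regression, multiple testing and best-fit selection

* **p-values** come from the overall regression F-test; for a linear fit
  this is algebraically the two-sided t-test on the slope (the test suite
  verifies the equivalence to 1e-10 relative tolerance, and agreement with
  a label-permutation null within Monte-Carlo error).
* **Bonferroni divisor** — the number of models screened per site: the
  descriptor count of the selected sets, doubled when quadratic screening
  is on (each scale is tested under two model orders).  Correction is per
  site; no cross-site correction is applied, since each site is its own
  hypothesis family.
* **RMSE** is √(SSE/n) over the n = 20 points.
* **Best-fit replacement** — a challenger that also passes the adjusted
  cutoff replaces the incumbent iff its RMSE is smaller and
  F = (RMSE_inc/RMSE_chal)² exceeds the upper `f_alpha` (default 0.05)
  critical value of the F distribution on (n − q_inc, n − q_chal) degrees
  of freedom, q being the number of fitted coefficients.  Ties favor the
  incumbent, i.e. the earlier descriptor in scan order — which is the point
  of the Set 1 → 4 ordering: a composite or discrete descriptor wins only
  by fitting *significantly* better than a simple one.  For the nested
  linear-vs-quadratic choice on the same descriptor, the standard
  extra-sum-of-squares F-test is used instead, and the quadratic candidate
  is offered at all only when that test favors it.
* **Quadratic trend sign** is the Pearson correlation between fitted values
  and descriptor values (retained quadratics are curved but
  near-monotonic); linear trend is the slope sign.
* **Degenerate sites** — a response with fewer than 3 distinct values
  (e.g. a strictly one-hot conserved site) cannot support a 2- or
  3-parameter regression and is skipped, landing in the unexplained
  classes; a constant response inside a fit yields p = 1 and is never
  retained.

## Synthetic data generator

The generator produces the three archetypes the screen must separate, on
the ΔΔG scale unless asked otherwise:

* **planted** — response = slope·d + ε, ε ~ N(0, noise_sd).  In the
  standard mixture, |slope| is set to 1/sd(descriptor) so the noise-free
  response has unit spread and `noise_rel` (default 0.1) is directly the
  noise-to-signal ratio; trend signs and descriptors are drawn uniformly
  from the selected sets.
* **null** — i.i.d. Gaussian responses, the type-I-error case.
* **conserved** — one-hot sites (as preference tables) or wild-type-0 /
  substitution-10 rows (inside ΔΔG mixtures), giving k* ≈ 1.

The default mixture is 60 % planted / 30 % null / 10 % conserved over 500
sites, a composition chosen to exercise recovery, error control and
tolerance flagging in one table at a size that screens in about a second.
Alignments are sampled column-wise from explicit amino acid profiles with
optional gap fraction; the query (first record) is the profile mode.  All
generators take explicit seeds and share no global state.

What the generator does **not** emulate: sequencing-depth noise and library
construction biases of real deep mutational scans, phylogenetic correlation
between alignment rows (rows are i.i.d. draws), epistasis, and coevolution
between sites.  Passing the recovery tests therefore shows the estimator is
correct under its own assumptions (independent Gaussian noise on the
response scale, independent sites), not that real proteins meet those
assumptions; on real data the explained fraction is far below the ~100 %
recovery seen at noise-to-signal 0.1.

## Numerical choices

* OLS via `numpy.linalg.lstsq` on the explicit design matrix; an exact fit
  (SSE = 0) reports p = 0 and always displaces an imperfect incumbent.
* F and t tail probabilities via `scipy.stats`; the test suite re-derives
  them independently through the regularized incomplete beta function.
* k* uses only nonzero frequencies in the entropy sum, so one-hot sites hit
  the 1.0 endpoint exactly.
* B-factor annotation edits PDB text in place by fixed column positions
  (61–66), preserving every other byte of every record; it refuses input
  with no ATOM/HETATM records and raises when the value mapping and the
  chain share no residue number (the usual symptom of a numbering offset).

## Known limitations

* Published per-protein benchmark percentages from the literature depend on
  the external deep-sequencing datasets and the exact descriptor numbers
  used there; with this package's documented default scales such
  comparisons are order-of-magnitude only, and they are not part of the
  test suite.  The binding checks are the analytic endpoints, closed forms,
  error-control and recovery simulations, and oracle equivalences above.
* One descriptor per site: sites shaped by several properties at once, or
  by interactions between sites, are reported unexplained.
* The F-based replacement between non-nested models on the same data is a
  pragmatic variance-ratio rule, not an exact test; it is used only to
  arbitrate among fits that already passed the significance cutoff.
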