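# Methods

## The experimental design the package models

A biparental cross between two inbred lines — labelled L (the parent
carrying the trait-increasing alleles, e.g. a long-grain cultivar) and S
(a short-grain donor) — is advanced to an F2, where every locus segregates
1:2:1. Individuals with the most extreme phenotypes at both tails are
pooled into two DNA bulks and sequenced together with both parents. At a
marker linked to a causal locus, phenotypic selection skews the bulks'
allele frequencies in opposite directions; at unlinked markers, both bulks
are random draws from the same F2 population and their expected allele
frequencies are equal. The association scan is a search for genomic
intervals where the between-bulk allele-frequency contrast exceeds what
segregation plus sequencing noise can produce.

## Per-site statistics

With `Laa`/`Saa` the read depths supporting the L- and S-parent allele in
the L bulk (`Lab`/`Sab` in the S bulk):

    SNPindex(aa) = Laa / (Laa + Saa)
    SNPindex(ab) = Lab / (Lab + Sab)
    ΔSNPindex    = SNPindex(aa) − SNPindex(ab)

and with `Aaa … Tab` the A/C/G/T base frequencies per bulk:

    ED = sqrt((Aaa−Aab)² + (Caa−Cab)² + (Gaa−Gab)² + (Taa−Tab)²)

ΔSNPindex requires parental orientation (the allele carried homozygously
by the L parent defines the index); ED does not, which is why the ED
filtering track never consults the parents. ED is raised to a power `k`
(default 2, "quadratic") before fitting: squaring shrinks the many small
background values relative to peak values near 1–2. `k` is read literally
as 2 rather than the 4–5 some pipelines use; it is a config knob.

Division-by-zero sites raise exceptions rather than returning 0/NaN —
the filtering contract must be honoured upstream.

## Filtering ledgers

Each track removes sites under a fixed precedence (first matching reason
wins), so every site lands in exactly one bucket and
`retained = total − Σ removed` holds identically:

* SNP-index track: `multi_allelic` (>1 ALT allele) → `identical_in_bulks`
  → `low_depth` (either bulk's oriented depth < 4) →
  `parent_uninformative` (parents not homozygous for opposite alleles).
* ED track: `low_depth` (any bulk's total base depth < 4) →
  `identical_in_bulks` (base-frequency vectors exactly equal, i.e. ED = 0)
  → `multi_aligned` (>1 ALT allele).

"Identical in bulks" is operationalised as *exact* equality of read
fractions at integer-depth resolution (integer cross-multiplication, no
floating point). A looser genotype-call rule (calling each bulk hom/het by
thresholding its read fraction and discarding sites with equal calls) was
evaluated and rejected: at realistic depths it removes essentially every
null site (both bulks called heterozygous) and leaves a retained set
conditioned on extreme ΔSNPindex, which inflates the windowed statistic
genome-wide and destroys the calibration of the null envelope.

Counts are precedence-dependent; the ledger records the order used.

## Sliding-window fitting

Windows are 1 Mb advanced in 10 kb steps, anchored at position 1 of each
chromosome, truncated at the chromosome end. Two fits are available:

* `mean` — unweighted average of the statistic over in-window sites
  (default for ΔSNPindex);
* `distance_weighted` — tricube kernel `(1 − (d/h)³)³` with `d` the
  distance to the window centre and `h` half the window size (default for
  ED²), the package's reading of distance-based fitting; a lone site
  anywhere in the window reproduces its own value, and the degenerate
  all-weights-zero case falls back to the unweighted mean.

Windows with no sites are explicitly missing (NaN) and excluded from all
threshold constructions. In the pipeline, windows with fewer than
`min_sites_per_window` (default 10) retained SNPs are additionally treated
as missing for thresholding and region calling: truncated chromosome-tail
windows hold one or two SNPs whose site-level noise inflates both
statistics at the same windows and otherwise produces coincident spurious
excursions in both tracks.

## Thresholds

* **ΔSNPindex null envelope.** Monte-Carlo simulation of the no-QTL null:
  each bulk's pooled allele frequency is `Binomial(2·bulk_size, ½)/2n`
  (free F2 segregation among the bulked individuals), reads are binomial
  at the mean observed bulk depth, and the envelope is the |Δ| quantile at
  the requested levels (90/95/99%; 100,000 replicates by default). Region
  calling uses the 99% level, two-sided (|fitted Δ| ≥ threshold). Because
  the envelope is built from single-site sampling while the tested values
  are window averages of positively correlated sites, it is conservative
  at the window level.
* **ED median + 3·SD.** `median + 3·sd` (sample SD, n−1) of all
  non-missing fitted ED² values genome-wide — the genome-wide significance
  rule, and the default ED region threshold.
* **ED 99% quantile.** The empirical 0.99 quantile (linear interpolation)
  of the fitted values, provided to refine broad significant regions down
  to their summits (`ed_threshold_rule='quantile_99'` or `'refined'`,
  which requires clearing both rules). Refinement trades coverage of the
  causal locus for narrowness — in simulation the refined regions
  (~0.3 Mb) are narrower than the sampling jitter of the peak position
  (~0.5 Mb) and frequently exclude the true locus, while the median+3·SD
  regions (~1–2.5 Mb) contain it; hence the wider rule is the default
  candidate set.

A caveat on median+3·SD under a pure null: the fitted ED² field is
approximately a squared Gaussian (drift) process, whose heavy right skew
means the empirical 99th percentile of fitted values can exceed
median+3·SD; occasional single-track null excursions are expected and are
screened out by the track intersection, which is the package's final
candidate set.

## Region conventions

A region is a maximal run of consecutive above-threshold windows, reported
as [first window start, last window start]; a single-window excursion is a
point region. Region length is `(end − start)/1e6` Mb (2 decimals in
tables) — together these are the only conventions that reproduce published
BSA-seq interval lengths from their printed step-aligned endpoints
(25,530,000 bp ⇒ 25.53 Mb, 30,000 bp ⇒ 0.03 Mb) while giving point regions
length 0. Runs separated by even one below-threshold window stay separate
(no gap bridging). Reported coordinates are 1-based inclusive; BED output
is 0-based half-open. Gene counts use ≥1 bp overlap.

## The simulator

`SimConfig` defaults are the study conditions the statistics were designed
for: 1,307 F2 individuals; bulks of 50; pooled bulk depth Poisson(70);
parent depth Poisson(35); sequencing error 0.001/read (symmetric toward
the other allele); one additive QTL with PVE 0.5485.

* **Meiosis**: crossover count per chromosome ~ Poisson(map length in
  Morgans), positions uniform on the map, no interference (Haldane). The
  map density default is 4 cM/Mb.
* **Phenotype**: `y = μ + a(g−1) + e`, `g` ∈ {0,1,2} L-allele dosage at
  the QTL, `e ~ N(0, σe²)`; `a = √(2·PVE)·σp` and `σe = √(1−PVE)·σp` so
  the additive variance `a²/2` (F2 frequencies 1:2:1) is the configured
  fraction of total variance σp². Scale: μ = 10.2 mm, σp = 1.0 mm, so
  μ ± 3σp spans the parental grain-length range (7–13 mm). No dominance
  (a config hook is reserved); only PVE is published for the motivating
  locus.
* **Bulks**: the `bulk_size` largest/smallest phenotypes; ties broken by
  ascending individual index, L pool filled first so the pools are
  disjoint even under ties.
* **Reads**: per site and pool, depth ~ Poisson(mean), L-allele reads
  ~ Binomial(depth, p(1−ε) + (1−p)ε).
* **Genome**: twelve 2.5 Mb chromosomes, markers every 6 kb (4,992 sites),
  QTL at chr1:1.25 Mb. The QTL-bearing chromosome is ~1/12 of the genome —
  the proportion one rice chromosome occupies — which matters because the
  median+3·SD rule needs most windows to be genuine background: on a
  single-chromosome genome the selection plateau inflates the SD past the
  maximum fitted value and no ED region is callable. Problem sizes here
  (and in the test suite: 20-replicate null-calibration and recovery
  suites) are the package's own desk-scale choices.
* **Imperfections**: a configurable fraction of sites is emitted
  parent-uninformative (variant only in the bulks; default 10%), with a
  spurious third allele (default 0.5%), or in coverage dropouts (bulk
  depth ~2; default 1%), so every filtering bucket has realistic material.

What the simulator does **not** model: dominance and multi-QTL epistasis;
crossover interference; mapping/alignment artefacts (multi-mapping reads,
indels, reference bias); depth heterogeneity beyond Poisson plus dropout;
GC or library biases; genotyping-caller quirks in GT/AD fields. Passing
recovery tests therefore demonstrate the pipeline's statistical behaviour
under clean segregation and sampling noise, not robustness to real
sequencing artefacts.

## Numerical and interface choices

* Quantiles use linear interpolation (numpy default), documented because
  "the 99 quantile" is otherwise method-silent.
* Envelope and simulator RNG streams are spawned independently from the
  master seed (changing envelope replicates does not perturb the cross);
  identical config + seed gives byte-identical output files (no
  timestamps in artifacts).
* Exact integer arithmetic wherever identity matters: ledger accounting,
  identical-in-bulks tests, VCF round trips.
* Multi-allelic records are kept at read time (with allele count) so the
  filter ledgers can count them; indel records are skipped at read time —
  the statistics are defined on single-base substitutions.
* The null envelope is computed at the mean observed bulk depth (scalar),
  not per window; per-window depth-specific envelopes are a possible
  refinement.

## Known limitations

* The intersection under default rules is ~1–2.5 Mb at the simulated
  design — candidate-region scale, not fine-mapping scale; narrowing to
  gene scale needs the quantile refinement (with its coverage trade-off)
  or additional markers/recombinants outside this package's scope.
* The identical-in-bulks rule is exact-equality; real pipelines built on
  genotype callers will bucket different (typically much larger) numbers
  of sites under "identical", so ledger magnitudes are not comparable
  across operationalisations.
* ED-track thresholds depend on the fitted-value distribution and hence on
  genome composition; a genome dominated by one selected chromosome needs
  `ed_threshold_rule='quantile_99'` or a larger null background.
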