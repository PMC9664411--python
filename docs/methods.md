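# Methods

## The assay and its model

`exciseq` analyses targeted long-read amplicon sequencing of a dual-guide
CRISPR exon-excision locus. Two SaCas9 guides (NNGRRT PAM, R = A or G) flank
a disease exon; simultaneous cleavage and NHEJ repair excise the exon and
fuse the flanking introns. A single PCR amplicon spanning both cut sites is
sequenced with high-accuracy long reads (CCS-style), and every read is
assigned to exactly one editing-outcome category:

| category | molecule |
|---|---|
| `unedited` | intact amplicon, both guide sites present |
| `indel5` / `indel3` / `indel_both` | indel at the 5ʹ and/or 3ʹ cut site, exon retained |
| `delta_exon` | productive excision: introns fused at the cut sites |
| `inversion` | inter-cut fragment re-inserted in reverse orientation |
| `aav_integration` | AAV vector backbone sequence inserted at a break |
| `unclassified` | feature evidence matches no category pattern |

### Locus model

Coordinates are 0-based, half-open, on the + strand of the amplicon
reference. The blunt double-strand break is placed 3 nt 5ʹ of the PAM
(standard Cas9 biochemistry; the offset is a module constant). Predicted
products are `deletion = ref[:cut5] + ref[cut3:]` and `inversion =
ref[:cut5] + revcomp(ref[cut5:cut3]) + ref[cut3:]`.

### Feature derivation

Classification rests on diagnostic k-mers (default k = 25):

- **intact5 / intact3** — k-mers centred on each cut site of the unedited
  reference;
- **fusion** — k-mers straddling the seam of the deletion product;
- **inversion_left / inversion_right** — k-mers straddling the two junctions
  of the inversion product;
- **exon_internal** — k-mers interior to the exon (≥15 nt margin from the
  exon boundaries so cut-site indels cannot clip them);
- **aav:\<vector\>:\<fwd|rev\>** — every k-mer (stride 1, deduplicated) of
  each AAV backbone in both orientations.

Each junction feature carries three staggered window copies (shifts of
±4 nt, automatically narrowed for small k so every window keeps ≥⌊k/3⌋ bases
on both sides of its junction); a local cluster of sequencing errors in one
window then rarely blinds the feature. At build time every edit-diagnostic
k-mer (fusion, inversion, AAV) is checked for absence from the unedited
amplicon within the matching tolerance; a collision raises an error, since
such a feature set could not distinguish edited from unedited molecules.

### Matching and decision procedure

A feature is *present* in a read when any of its k-mers occurs in the read
or its reverse complement within `max_dist` Levenshtein edits (default 2,
substitutions and indels). The category is assigned by fixed precedence: AAV
evidence first (backbone k-mers are provably absent from the locus, the most
specific evidence), then inversion junctions (an inverted molecule retains
exon sequence, so it must outrank the exon-based rules), then fusion without
exon (productive excision), then the intact-site pattern (both disrupted
with exon retained → `indel_both`; one disrupted → `indel5`/`indel3`; both
present → `unedited`); anything else is `unclassified`. Reads are never
double-counted; percentages are reported over all classified reads,
including `unclassified`.

**Detection limit.** "Site disrupted" means the intact-site feature is not
matched within `max_dist`. A cut-site indel of size ≤ `max_dist` is therefore
indistinguishable from sequencing error and is called `unedited`; similarly,
a deletion product with a fusion-seam indel larger than `max_dist` loses the
fusion k-mers and falls through to `unclassified`. Both limits are inherent
to presence/absence k-mer classification and are exercised explicitly in the
test suite.

### Exact seed-indexed matching

AAV feature sets contain thousands of stride-1 k-mers, so naive per-k-mer
alignment of every read is quadratic in practice. The matcher instead uses
an exact q-gram screen: a k-mer aligned within d edits retains ≥ k−d matched
characters in at most d+1 runs and therefore shares at least
`(k−d) − (d+1)(q−1)` exact q-grams with the read, at mutually consistent
diagonals (pairwise diagonal difference ≤ d, positions within one k-mer
span). q is chosen as the largest value guaranteeing ≥4 such seeds (q = 7
for k = 25, d = 2, guaranteeing 5). Only seed clusters meeting the
guaranteed count are verified with edlib infix alignment; everything pruned
provably cannot match. The direct per-k-mer path is retained and the two are
cross-checked against each other and against an independent dynamic-program
oracle in the tests.

### Demultiplexing and filtering

Libraries carry asymmetric internal 8-mer barcodes on both primers
(`fwdBC + insert + revcomp(revBC)`; reverse-oriented reads are the reverse
complement of that). Assignment requires both end windows to match one
sample's pattern within `max_mismatch` substitutions (default 1, no indels);
barcode sets must be pairwise separated by more than `2·max_mismatch`
substitutions, checked at load. Barcodes are trimmed on assignment;
unassigned reads are reported and never classified.

Mean read quality is computed on the error-probability scale,
`Q_mean = −10·log10(mean(10^(−q/10)))` — the defensible error-rate reading
of a minimum-average-quality (maq) cutoff; the arithmetic Phred mean is
available as an option. Defaults: mean quality ≥ Q20 and length ≥ 400 bases,
both inclusive, with length measured after barcode trimming.

## The synthetic-read generator

The generator emulates the study conditions of the assay: an 833 bp amplicon
with cut sites 387 bp apart (446 bp excision product) flanking a 213 bp
exon, 8-mer barcode pairs, random read orientation (50/50), and an i.i.d.
error model in the Q20–Q30 band (default 1% total error split 2:1:1
substitution:insertion:deletion, qualities uniform on 27 ± 3). Default
category proportions are the mid-points of the reported outcome ranges for
CRISPR-treated cardiac muscle — indel5 11.5%, indel3 2%, indel_both 0.5%,
delta_exon 0.55%, inversion 0.05%, AAV integration 0.75% — with unedited
absorbing the remainder (84.65%) so the proportions sum to exactly 1.

Cut-site indel sizes are geometric (p = 0.3) with deletions:insertions 3:1,
truncated to 3–25 nt. The lower bound sits one edit above the classifier's
default tolerance: a 1–2 nt indel is, by the detection-limit argument above,
definitionally unobservable to the k-mer classifier, and the generator's
purpose is ground-truth recovery testing, so its truth labels are restricted
to molecules whose category is in principle detectable. Draws are further
rejected (and redrawn) if repetitive context collapses the edited site to
within 2 edits of the intact site (e.g. a 3 nt deletion inside a
homopolymer), or if the chance indel sequence lands within 2 edits of a
fusion or inversion junction signature (those junctions share one flank with
the cut site, so a short random insertion occasionally reconstitutes one) —
in either case the molecule's evidence is genuinely ambiguous and must not
carry a plain indel truth label. Setting `min_size=1` and
`ensure_disruption=0` lifts these guards for studying the blind spot.

Deletion-product (delta_exon) molecules are seamless by default — the
assay's major product. Fusion-seam indel presets (−4 nt downstream, −11 nt
upstream, the cloned repair variants) are available behind
`junction_indel_prob` and are used in tests to document that seam-damaged
productive edits classify as `unclassified`. AAV events insert a fragment of
a backbone (uniform 100–1,600 nt, either orientation, capped so the molecule
stays ≤1,750 nt — long templates amplify poorly) into either the completed
deletion junction or a single 5ʹ cut.

**What the generator does not model:** PCR amplification bias against long
templates (reported to make observed AAV rates underestimates), chimeric
reads, instrument-specific error kinetics, and barcode cross-talk. Recovery
tests therefore demonstrate correctness against *simulated* truth under
these idealisations, not against biological truth.

## Parameter optimization

`optimize_params` grids (k, max_dist) and minimises, on an untreated control
library, the fraction of reads assigned to any non-unedited category (the
false-positive rate; `unclassified` counts as a false positive). Ties break
toward larger max_dist (more error tolerance), then smaller k. Grid cells
whose feature set fails the diagnostic check for the locus (typical for
small k with large max_dist) are reported as infeasible and excluded.

## Quantification arithmetic

Standard curves are least-squares fits `Cq = m·log10(copies) + b` (≥3
dilution points, m < 0 required), with amplification factor `A = 10^(−1/m)`
and efficiency `E = A − 1`. Technical replicates are averaged on the Cq
scale before conversion. The exon-skipped fraction is
`100·dex/(dex + fl)`. Vector genomes per host genome divides AAV copies by
single-copy-gene copies; an optional flag divides the denominator by ploidy
(default 2) to report per diploid genome, off by default. A gDNA mass
standard converts at 6.6 pg per diploid mouse genome. Pfaffl ratios use
amplification factors in (1, 2.2] and the ΔCq convention control − sample,
so ratios > 1 mean the target is up in the sample.

## Problem sizes and numerical choices

- Recovery tests use n = 5,000 reads (zero-error, exact recovery) and
  3 × 20,000 reads (noisy recovery, each category within 3 binomial SE of
  truth); the control library uses n = 2,000. These sizes give the minor
  categories (0.05–0.75%) expected counts of 10–150 per library while
  keeping the full suite fast.
- Amplicon-size modes are taken as the most frequent exact length within the
  most populated 10 bp bin, which is stable against indel jitter yet exact
  for unimodal error-free bins.
- Percentages print to 2 decimals, 4 decimals below 0.01%.
- Quality-filter and length boundaries are inclusive, with a 1e−9 guard on
  the Phred comparison against floating-point log10 round-off.
- All randomness flows through a single `numpy` Generator seeded from the
  config, so libraries are byte-identical across reruns.

## Known limitations

- Junction indels at or below the matching tolerance are invisible
  (absorbed into `unedited`), consistent with treating the few-percent
  background at a weakly cut site as noise floor.
- Productive-excision reads with large seam indels are `unclassified`, not
  `delta_exon`; alignment-based breakpoint refinement is out of scope.
- Barcode matching tolerates substitutions only; reads with an indel inside
  a barcode window are unassigned (~a few percent at 0.5% indel rates).
- The classifier reports presence/absence evidence, not per-allele indel
  spectra.
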