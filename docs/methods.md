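# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the design choices made where the conventions of the field are informal.

## 1. Conserved signature indel (CSI) detection

### Model

A CSI is an insertion or deletion restricted to a monophyletic in-group and
embedded in conserved sequence. Published CSI surveys identify them by
visual inspection of curated alignments; this package replaces each informal
criterion with an explicit, parameterised rule so that detection is
reproducible and testable.

**Conservation.** A column is conserved iff a single amino acid occurs in at
least `conservation_threshold` (default 0.8) of the rows considered. Gaps
and the unknown residue `X` count in the denominator and never toward the
majority, so a column that is identical in the sequences that have it but
gapped in many others is *not* conserved — matching the visual judgement
that a conserved block must be present across the whole alignment. The 0.8
default is a deliberate surrogate for "conserved by eye"; no community
numeric standard exists, so the threshold is exposed and the monotonicity of
detection in it is tested. Conservation is scored across both groups by
default (`conservation_scope="both"`); an in-group-only mode is provided for
surveys where the out-group panel is deliberately diverse.

**Candidate blocks.** Tolerances are converted to whole-record counts:
`allowed_out = floor(max_outgroup_sharing · n_out)` (raised to ≥ 1 by
`allow_isolated_exception`, which models the occasional lone database hit
sharing an indel) and `allowed_in = floor(max_ingroup_missing · n_in)`.
A column qualifies for an insertion when at least `n_out − allowed_out`
out-group rows are gapped *and* at least one in-group row bears a residue;
deletions use the converse pattern. Candidates are maximal runs of
qualifying columns. The residue-side tolerance is enforced at interval
level — at most `allowed_in` in-group records (insertion) or `allowed_out`
out-group records (deletion) may lack any residue in the interval — rather
than per column, because real inserts are ragged: a 5–7 residue in-group
insert leaves its trailing columns gapped in the shorter members, and a
per-column residue requirement would truncate the block and misreport the
size range. Sizes are min–max of per-sequence non-gap counts over the
residue-bearing group (in-group for insertions, out-group for deletions;
an in-group count would be identically zero for deletions).

**Flanks.** Conserved columns are counted in windows of `flank_window`
(default 35) columns immediately left and right of the candidate, truncated
at alignment edges; both counts must reach `min_conserved_flank` (default
5). The defaults sit at the conservative end of the working rule of thumb
for signature indels ("5–6 conserved residues within 30–40").

**Specificity.** At interval level, a sequence carries an insertion iff it
holds ≥ 1 residue in the interval and carries a deletion iff it holds none.
`strict` = all in-group carry, no out-group does; `tolerant` = violations
within the tolerances, with every violating id listed in the record;
otherwise the candidate is rejected. Treating one stray out-group residue in
a 30-column block as "sharing" is deliberately conservative — the cost is a
tolerant rather than strict verdict, never a silently cleaned signal.

**Reporting.** Coordinates are half-open 0-based internally and 1-based
ungapped reference-protein positions in all outputs. The mapping from column
to reference position is the cumulative count of non-gap reference
characters (a reference gap maps to the nearest preceding residue; 0 before
the first). The reported region runs from the leftmost conserved column of
the passing left flank window to the rightmost of the right one — a
reproducible stand-in for the hand-chosen excerpt bounds of published
signature figures, which is why tests check that the indel lies *within*
the region rather than demanding particular endpoints. For deletions, which
have no reference residues, `indel_ref_start`/`indel_ref_end` bracket the
deletion point (last residue before, first after).

**Signature blocks** use the dash-for-identity display convention: the
reference on the top line, `-` for identity with the top line, the residue
letter for a difference, and `.` for a gap opposite a reference residue.
The encoding is lossless (`signature_to_residues` inverts it), which the
suite verifies for every emitted record. **Validation segments** are
ungapped reference subsequences of `validation_segment_length` residues
(default 80, clamped to 60–100) centred on the indel and always containing
it, intended for external homology screening of the signature region; that
screening itself (e.g. BLASTp against a sequence database) is out of scope —
specificity is computed only within the supplied out-group panel.

### Degenerate inputs and tie-breaks

Adjacent candidate blocks separated by ≥ 1 non-qualifying column are
distinct candidates; candidates are ordered by start column with insertions
before deletions at equal start. An all-gap column has majority residue
`-`, majority fraction equal to its gap fraction, and is never conserved.
Candidates whose size range lies outside `[min_indel_size, max_indel_size]`
are dropped before flank evaluation.

## 2. Operon prediction and arrangement comparison

Intergenic distance on 1-based inclusive coordinates is
`start(b) − end(a) − 1`: abutting genes give 0 and overlapping coding
regions give negative values, consistent with GFF/GenBank conventions.
Operons are maximal runs of consecutive same-contig, same-strand genes with
each consecutive distance strictly `< linkage_bp` (default 200, the
standard genomic-context heuristic); negative distances always link, since
overlap is itself strong evidence of co-transcription. The `merge_bp` rule
(default 100, also strict) applies only to `merge_adjacent_operons`, which
joins adjacent *externally supplied* predicted units (the situation where a
database's operon table splits one transcription unit in two); a
strand-consistent gap ≥ `linkage_bp` found by the predictor itself is never
merged. Thresholds are strict inequalities, matching the "< 200 bp" /
"< 100 bp" phrasing of the underlying heuristics.

Neighborhood extraction takes up to `k` genes either side of every copy of
the anchor family on its contig and normalises orientation: an anchor on the
reverse strand has its window reversed and strands complemented, so
"downstream" always reads to the anchor's right. Arrangement comparison is
exact equality of the ordered (family, strand) tuple; with the default
`anchored=True` the tuple is taken from the anchor onward for the length of
the reference, which is the survey question actually asked ("is the cluster
organised identically downstream of the anchor?") and insulates the count
from genome-specific genes upstream. An empty reference matches vacuously.
Family labels come from the annotation or a user-supplied locus→family map,
never from homology search — the module is download-free by design.

## 3. CXXC scanning

A hit is any position `i` with `seq[i] = seq[i+3] = C`. By default the two
X positions admit any residue including cysteine, and overlapping hits are
all reported; published motif counts do not state either policy, but real
zinc-finger CXXC pairs are disjoint, so the default reproduces them while
`strict_x` and `overlapping=False` (greedy left-to-right) cover the
alternative readings. Grouping motifs into zinc-finger elements is not
attempted: the motif-to-element mapping is structural knowledge not
derivable from sequence alone.

## 4. Synthetic data: what it does and does not emulate

The family generator uses an i.i.d. column model: a base residue per
column, a chosen fraction of columns invariant (default 0.5), independent
per-sequence substitution in variable columns (default probability 0.3),
and the planted indel realised directly in the gap structure with
`flank_conserved_run` (default 6) columns forced invariant on each side.
Defaults — 24 in-group, 12 out-group, 600-residue proteins — mirror the
scale of a curated signature alignment for a bacterial repair protein with
a genus-level in-group and a representative out-group panel. Substitution
noise uses common random numbers (one uniform draw per cell, compared to
the probability), so raising `substitution_prob` only ever adds
substitutions — making noise-monotonicity properties exact rather than
statistical. Null families plant "shared" gap blocks carried by exactly
half of each group, which are guaranteed non-differential under any
tolerance below 0.5.

This model intentionally omits phylogenetic correlation, rate
heterogeneity, indel drift and alignment error. Passing tests therefore
demonstrate that the detector implements its stated criteria exactly, not
that those criteria are robust to misalignment or to deep phylogenetic
structure; on real alignments the conservation threshold and tolerances
are the knobs that absorb those effects.

The genome generator lays genes left to right, so planted intergenic gaps
are exact by construction. Defaults emulate a 26-genome panel with 24
genomes carrying a four-gene same-strand cluster (gaps 5–99 bp) downstream
of the anchor and two genomes in which only the first partner remains —
the characteristic "conserved operon with a minority rearrangement"
pattern. Options plant a negative (overlapping) gap and place the whole
neighborhood on the reverse strand to exercise orientation normalisation.
The proteome generator excludes cysteine from background residues and
plants motifs on disjoint 4-residue tiles, so planted CXXC counts are
exact under every scanning policy.

## 5. Problem sizes used in verification

The shipped verification runs 100 planted replicate families (sizes cycling
through 1, 2, 16, 30 and 65 residues, alternating insertions and deletions)
plus 100 matched null families at the default study conditions, 500 random
small alignments and 500 random sequences against brute-force oracles, and
one 26-genome panel — sizes chosen to exercise every rule and boundary while
keeping the full suite and the acceptance script each under a few seconds
on one CPU.

## 6. Known limitations

* Specificity is judged against the supplied out-group panel only; a CSI
  can always be invalidated by a wider database screen, which is why
  validation segments are exported.
* Region endpoints are a convention (flank-to-flank), not a canonical
  quantity; two reasonable implementations may disagree on them while
  agreeing on the indel itself.
* The operon rules are heuristics on gene geometry; they do not model
  promoters, terminators or expression data.
* GenBank feature-table input is the NCBI assembly TSV flavour; full
  GenBank flatfile parsing is not implemented (convert, or use GFF3).
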