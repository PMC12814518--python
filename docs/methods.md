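# Methods

## Problem setting

A phage-assisted noncontinuous selection (PANCS) couples the assembly
of a phage-borne protein variant to phage propagation: only phage whose
variant assembles trigger expression of the essential phage gene *gIII*
in the host and can complete an infection cycle. Serial passaging of a
site-saturation library therefore enriches assembly-competent variants
and depletes defective ones, and per-passage amplicon sequencing of the
mutagenized window converts that enrichment into a per-variant fitness
readout. `pancsel` implements the analysis chain (counting →
thresholding → fitness → enrichment mapping) and a generative simulator
of the selection itself.

## Variant space

A library is described by a `LibraryDesign`: `n_positions` consecutive
mutagenized codons (default 3, residues 331–333, wild type `DRA`)
embedded between fixed nucleotide flanks. Variant identity for all
analysis is protein-level over the 21-letter alphabet (20 amino acids +
stop `*`), giving 21ⁿ variants; synonymous codon windows are collapsed
by summing counts. The genetic code is the standard table (the host is
*E. coli*); stop-containing variants are retained through counting and
fitness but flagged, and excluded only from the enrichment matrix. The
default flanks are synthetic stand-ins — any fixed A/C/G/T context can
be configured; the real amplicon context is experiment-specific.

## Read counting

Reads are single-end FASTQ (plain or gzip). The mutagenized window is
located by exact match of the upstream flank (forward strand first,
then reverse complement), and the downstream flank must follow at
exactly `3·n_positions` nucleotides. Failures are tallied per passage by
reason (`flank_not_found`, `bad_spacing`, `ambiguous_base`,
`bad_window_length`), so accepted + rejected = total reads always
reconciles. No mismatch tolerance and no base-quality filtering are
applied: the window sits inside fixed context, sequencing errors
surface either as rejected reads or as rare spurious variants that the
detection threshold suppresses. A mismatch-tolerant or indel-aware mode
is deliberately out of scope.

The detection threshold retains variants with ≥ `min_input_reads`
(default 10) reads in the input library; the census of detected /
retained / dropped variants is recorded. When several selection arms
share one input library, the pipeline analyzes the intersection of the
arms' retained sets so cross-arm comparisons are defined variant by
variant.

## Fitness and classification

Per passage, a variant's abundance is its fraction of accepted reads
over retained variants. The fitness score is
`log10(f_final / f_input)` using the first (input) and last passage;
intermediate passages feed the trajectory output only. Choices worth
making explicit:

- **Frequencies, not raw counts**, so unequal per-passage depths cancel.
- **Base-10 log**, so −1.0 reads as "tenfold frequency drop".
- **No pseudocounts**: zero final reads is an explicit `depleted` class
  rather than a large negative number; `positive` means fitness > 0 and
  `negative` covers the rest. The three classes partition the retained
  set.
- **Lowered-assembly prediction**: depleted, or fitness ≤ −1.0 with the
  bound inclusive. Scores near zero are known not to discriminate
  assembly well, but no third "uncertain" class is introduced — the
  boolean encodes the one rule the classification uses.
- An all-zero final column (fully purged arm) yields all-depleted
  records rather than an error; the standalone `fractions` operation
  stays strict about zero-total columns.

Fold propagation (output titer / input titer) is computed from titers
and reported alongside; arm comparison reports the positive-fraction
ratio, the change in depleted count, and the rescued set (depleted
without the chaperonin, not with).

## Enrichment matrix

For each position and amino acid, the score is the base-10 log of the
ratio of occurrences among positive-fitness variants (intersected
across the chosen arms, stops excluded) to occurrences among all
retained starting variants. Occurrences are counted per position slot —
`DRD` contributes aspartate twice to the pooled "total" column, which is
computed from pooled counts, not by averaging per-position scores. Zero
numerator occurrences give a `zero_occurrence` sentinel (a crossed-out
cell); an amino acid absent from the starting set at a position gives
`not_in_library`. Under this literal count-ratio definition every
defined cell is ≤ 0 (positives are a subset of the starting set), which
shows depletion structure but not relative enrichment; the `centered`
mode subtracts `log10(|positive| / |starting|)` so values above the
library-wide retention appear positive. Output labels the mode; neither
mode is privileged.

## Serial-passage simulator

Each passage applies, in order: (i) a multinomial draw of `bottleneck`
phage (default 10⁵) from the current pool frequencies — `bottleneck=None`
substitutes the expectation, giving the closed-form deterministic limit
in which two-variant odds multiply by the ρ-ratio per passage; (ii)
optional hitchhiker acquisition; (iii) expected-offspring growth, where
each genome contributes in proportion to its propagation factor ρ(v),
followed by renormalization. One effective generation per passage is
assumed — fold propagation is measured per passage and no within-passage
kinetics are modeled. Sequencing is a multinomial draw of `read_depth`
reads per passage (including the input pool). A single seeded numpy
generator drives all draws, so identical parameters and seed give
bit-identical count tables.

**Ground truth.** ρ(v) = ρ_wt · 10^(−Σ_pos penalty(aa, pos)), with
per-(amino acid, position) penalties drawn once per library:
wild-type residues 0; stops 10 log-units per position (effectively
lethal at any buffering considered); other substitutions near-neutral
(uniform on [0, 0.2] log-units) with probability 0.13, otherwise
deleterious (uniform on [0.25, 1.3]). ρ_wt defaults to 1000, matching a
~1000-fold propagation advantage of an assembly-competent variant over
a defective one.

**Chaperonin buffering.** GroELS overexpression is modeled as a factor
`groels_buffer ∈ (0, 1]` multiplying each variant's log10 deficit
relative to ρ_wt (1 = no rescue; 0.5 halves every deficit; variants
fitter than wild type are untouched). This guarantees the +GroELS ρ is
never below the −GroELS ρ and reproduces the qualitative effect of
chaperonin overexpression: more positives, fewer depletions.

**Hitchhikers.** Spontaneous second-site mutations outside the
mutagenized window are modeled as a per-genome, per-passage acquisition
probability moving a genome into a parallel sub-pool of its variant
with ρ multiplied by `hitchhiker_boost`; their own sequence is not
tracked — they matter only through the inflated counts of the carrier
variant. The default rate is 0 so core analyses are hitchhiker-free.

**Default conditions.** The defaults — 3 passages, 10⁵ bottleneck,
read depth 450 000, input abundance log-normal with σ = 1.15 around
uniform, and the penalty mixture above — were chosen so that a
simulated default library resembles the shape of a real saturation
selection: roughly three-quarters to four-fifths of the 9261 variants
clear the 10-read detection threshold, most retained variants deplete
by passage 3, a few percent score positive without the chaperonin and
roughly two-to-three-fold more with it, and ~85–90% are predicted to
have lowered assembly. These are distributional targets, not calibrated
fits; per-seed numbers vary.

**What the simulator does not capture.** Infection kinetics and pIII
dose response; PCR and sequencing error (reads are emitted error-free
between exact flanks, so rejected-read tallies on simulated data are
zero); per-codon library composition biases (FASTQ emission uses one
canonical codon per amino acid); replicate structure or batch effects;
and any quantitative mapping from assembly efficiency to ρ. Passing
tests on simulated data therefore validate the analysis machinery and
its statistical behavior under the stated generative model, not the
biology of any particular library.

## Numerical choices

- Fitness is computed as `log10(f_final) − log10(f_input)`, which is
  exact at round decades (a tenfold drop gives −1.0 exactly).
- Frequency vectors are validated to sum to 1 within 1e−9.
- Sanger-style majority calls in the two-variant competition use argmax
  frequency with ties (≤ 1e−9) held at the previous call, so the
  deterministic 1:1000 / 10× case flips strictly after the odds cross 1.
- Detection-threshold boundary is inclusive (≥ 10 reads retained);
  `min_input_reads=0` is the identity.
- TSV outputs use fixed column orders and `%.6g` floats; JSON manifests
  are key-sorted — a config + seed fully determines the byte content of
  a bundle.

## Problem sizes in tests and the acceptance script

Simulation-backed checks use 300–1000-variant sublibraries at read
depths of 10⁴–10⁶ and Monte-Carlo loops of 100 seeds; the full
9261-variant library is simulated at the default depth for the
end-to-end selection summary. These sizes make every property check
sharp (e.g. Spearman recovery ≥ 0.8 at depth 10⁶ on 500 variants) while
keeping the whole suite fast on one CPU.
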