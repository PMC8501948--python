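# Methods

## Coordinate and strand conventions

Internally every coordinate is 0-based, half-open, on the top strand of the
locus; user-facing labels use the nick-relative convention (+1 = first base 3′
of the nick on the PAM strand). Edits are stored top-strand and converted to
the PAM-strand frame only where the biology demands it — label rendering,
PBS/RT construction, flap and PTD modelling. For a bottom-strand protospacer
the PAM-strand frame is the reverse complement of the locus; a top-strand
position *i* maps to *L − i*. We adopt the PAM-strand convention for "+n"
offsets throughout, matching the prime-editing literature; the alternative
(top-strand counting regardless of protospacer strand) would make labels
depend on which strand a reference happens to be written on.

SpCas9 geometry is fixed: the nick falls between protospacer positions 17 and
18, i.e. 3 nt 5′ of the NGG PAM, on the PAM strand. Multi-base substitutions
are modelled as equal-length ref/alt replacements rather than
deletion+insertion, which is what the `+1–3 CAA to ACC` naming style implies.

## Design engine

`scan_pam_sites` enumerates all 20-nt spacers adjacent to NGG on both strands
(regex with lookahead, so overlapping sites are found) in a fixed order: top
strand 5′→3′, then bottom strand by ascending top coordinate.
`candidate_pegrna_sites` keeps sites whose nick lies 5′ of the entire edit on
the PAM strand within `max_nick_to_edit` (default 30 nt — exposed as
configuration; we make no claim about what limit, if any, interactive design
tools enforce) and ranks by nick-to-edit distance with deterministic
tie-breaking (+ strand first, then coordinate), so identical inputs always
produce identical output.

Defaults: `pbs_len` 13 nt and `rt_homology_len` 13 nt, the mid-range values
of common practice (PBS 8–17, homology long enough to anneal reliably); both
are per-call parameters and config keys. PBS lengths below 8 are accepted —
small worked examples use them — but logged as outside the practical range.

Second-nick guides must sit on the opposite strand; their signed offset is
the nick-to-nick distance, positive 3′ of the pegRNA nick on its PAM strand
(the "+48"/"−60" style). The default search window is ±120 nt excluding ±10
nt: nicks closer than ~10 nt on opposite strands behave like a double-strand
break, and beyond ~120 nt the second nick stops helping. Both bounds are
configuration.

Golden-gate emission fills three slots — spacer, extension, second-nick
spacer — each as a top/bottom oligo pair with 4-nt 5′ overhangs. The shipped
overhang table (PX459-lineage BbsI convention for the spacer slot; distinct
pairs for the other slots) is an editable configuration default; the code
validates only the structural invariants that make one-pot directional
assembly work: overhangs exactly 4 nt and the three slot pairs mutually
distinct. Constructs without a genomic second nick (nuclease, and PE2) carry
a non-genome-targeting sham guide in the third cassette so the plasmid
assembles identically; the shipped sham sequence is a config default and its
non-targeting status is not verified here. The T7 promoter
(`TAATACGACTCACTATAG`) and SpCas9 scaffold are named constants, also
overridable. IVT primers: forward = T7 + spacer oligo + the first 15 nt of
the scaffold; reverse = reverse complement of the last `anneal_len` (≥ 15) nt
of scaffold+extension, reaching into the scaffold (with a logged warning)
when the extension is short.

## Flap model and the design oracle

`simulate_flap` rebuilds the edited allele **only** from pegRNA fields: it
checks the PBS against the genomic bases 5′ of the nick, treats
`revcomp`-decoded RT template as the synthesized flap, and re-anneals the
flap's terminal homology downstream. When the terminal homology k-mer occurs
at several positions (possible in random or repetitive sequence), the
occurrence nearest the expected junction (`nick + rt_len − homology_len`) is
chosen; this keeps the reconstruction exact without consulting the edit
itself. Agreement with `apply_edit` over randomized designs is the package's
central round-trip invariant.

PTD alleles join a flap *prefix* (edited segment + first `dup_len` homology
bases) directly to the unresected DNA at the break, optionally losing
`junction_del` bases at the junction. With no junction deletion the PTD is
strictly longer than the correct allele and always contains the full alt
allele. Note one degenerate identity: `dup_len = 1, junction_del = 1`
duplicates exactly the base it deletes, giving a sequence identical to the
correct allele — a genuine ambiguity of the end-joining model, not a bug.

## Read simulator

Reads are full-length amplicons (paired-end merging is upstream of this
tool), drawn i.i.d. from the class mixture, with a uniform per-base
substitution error (default 10⁻³, typical of merged short reads) and uniform
quality. Indel errors and quality variation are deliberately not modelled:
what is under test is the classifier's decision logic, not error-model
calibration. PTD duplication lengths default to uniform over
[1, rt_homology_len]; no claim is made that this matches any empirical
duplication-length distribution. Junction deletions default to zero.

Indel alleles (deletions centred on the nick; insertions of random bases at
the nick) are rejection-sampled until they are *identifiable*: an allele that
reproduces the edit signature, equals the unedited locus, or classifies as
anything other than `indel_other` under default parameters is redrawn (with
positional jitter for deletions). Without this, truth labels are not
well-defined — e.g. a random 1-bp deletion adjacent to an intended 1-bp
deletion differs from the correct allele by a single substitution, which no
read-level classifier can separate from a sequencing error.

## Classifier

Reads are orientation-normalised (edlib distance against the reference, both
orientations) and pass a minimum-length pre-filter (default: the smaller of
50 nt and 80% of the amplicon). Alignment is global with affine gaps
(match +2, mismatch −4, gap open −10, extend −1) via Biopython's
`PairwiseAligner`; the first optimal alignment is taken, giving deterministic
gap placement. Exact string equality against the reference and correct
alleles short-circuits the dynamic program for the large error-free majority
of reads.

The quantification window defaults to `[nick − pbs_len, nick + rt_len + 5]`
in target coordinates. Precedence, total and deterministic:

1. **WT** — no indel in the window against the reference, reference allele
   intact at the edit site, at most `max_window_mismatches` (default 3) stray
   substitutions elsewhere in the window;
2. **correct_PE** — the same against the correct allele, with the alt allele
   intact;
3. **PTD** — the read carries the edit signature and its alignment to the
   correct allele contains a window insertion sharing ≥ `ptd_min_match`
   (default 3) contiguous nt with RT-template-derived sequence;
4. **indel_other** — everything else.

The *edit signature* is the last `flank` nt of the PBS (default: all of it)
plus the edited segment through the alt allele plus `min(3, homology)` nt of
downstream homology — the PBS-plus-edit filter that defines "any intended
edit". Exact substring search is complemented by an alignment-based
generalisation: a read whose alignment to the correct allele has no operation
inside a guard neighbourhood (± 3 nt) around the edit also counts as carrying
the signature. The exact-only rule would systematically leak a few percent of
correct and PTD reads to `indel_other` at a 10⁻³ substitution error rate
(~20-nt signature ⇒ ~2% of reads carry an error inside it), biasing every
percentage; tolerating substitutions — but never indels — inside the window
keeps class recovery unbiased while leaving WT/correct discrimination strict
at the edit bases themselves. An exact-substring PTD rule (junction probe per
duplication length) is available behind `ptd_rule="substring"` for designs
where alignment-based insertion calling is undesirable.

Known limitations: PTDs with 1–2 duplicated bases are intrinsically
indistinguishable from short indels under the 3-nt template-match threshold
and are counted as indels; reads with sequencing errors exactly on the edit
bases (probability ≈ edit length × error rate) are conservatively demoted to
`indel_other`; substitution-only tolerance means real indel sequencing errors
(not simulated here) would be mislabelled.

`summarize` computes correct/WT/PTD percentages from counts and derives
`unintended = 100 − correct − WT` and `indel = unintended − PTD` by those
identities (never tallied independently), so the report arithmetic holds
exactly on any input; `any_intended` is the signature-carrying fraction.

## Problem sizes and determinism

The shipped verification uses 200-case design round-trips, a 200-design rule
audit, 5,000 error-free reads for truth-table agreement, and 20 × 10,000-read
simulations at 10⁻³ error for mixture recovery — sizes at which binomial
noise on a 10,000-read class percentage (σ ≈ 0.3–0.5 points) sits comfortably
inside the ±1.5-point recovery band. All randomness flows from explicit
seeds; rerunning any stage with the same seed is byte-identical.
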