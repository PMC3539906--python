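# Methods

## Enzyme model

An enzyme record holds a non-ambiguous palindromic hexamer recognition site,
a top-strand cut offset (0–6 bases into the site), and the derived cohesive
end. Cut geometry is assumed symmetric — the bottom-strand cut mirrors the
top-strand cut about the palindrome centre — so the overhang is always the
central segment between the two cuts: offset 1 gives a 4-base 5′ overhang
(`site[2..5]`), offset 5 the same 4-mer as a 3′ overhang, offset 3 a blunt
cut. Only 5′-cutting, 4-base-overhang enzymes are *hybrid-eligible*;
3′-cutters (SacI) and blunt cutters still participate in site mapping and in
palindromic junctions. Isoschizomers (same site, same geometry) are merged
into one record with synonyms; lookups accept any name.

Dam/Dcm sensitivity is modelled at two levels: a sequence-context heuristic
(site contains `GATC`, or `CCAGG`/`CCTGG`) and explicit per-row table flags
that override it. The override matters: BamHI's site `GGATCC` contains the
Dam context but the enzyme is not blocked by Dam methylation, whereas BclI
(`TGATCA`) is; the bundled table therefore carries explicit flags. With
`avoid_methylation` enabled the planner excludes flagged enzymes from
junction candidacy entirely rather than warning.

## Hybrid sites and site spaces

For an ordered compatible pair (A, B), the ligation product 6-mer is
`A.site[1] + overhang + B.site[6]` (1-based). It is palindromic iff A = B,
and the (B, A) product is the reverse complement of the (A, B) product —
which is why the scanner only ever scans the forward strand: the hybrid list
carries both orientations of every pair, and native sites are palindromes.
Identity pairs are reported as native palindromic sites, not hybrids.

Theoretical enumerations are done by brute force over all 4⁶ hexamers (or
4⁴ tetramers): 64 palindromic hexamers, 256 hexamers whose central 4-mer is
palindromic (the hybrid space, palindromes included), 16 palindromic 4-base
overhangs. With 256 site families the expected spacing is 4096/256 = 16 bp.

## Occurrence statistics

Windows of length 6 in an L-bp fragment are treated as n = L − 5 independent
Bernoulli trials with success probability p = 4⁻⁶ (uniform i.i.d. bases).
`prob_no_site`, `prob_single_site` and `prob_multi_site` are the binomial
zero/one/tail classes (via `scipy.stats.binom`); at L = 5000 they give
29.5 % / 36.0 % / 34.4 %. `prob_at_least_one` exposes both the exact
complement and the linear expected-count bound min(1, L·p) — the
back-of-envelope figure (24.4 % at 1 kb, 12.2 % at 0.5 kb) used when judging
whether a junction enzyme risks cutting inside its own module; exact ≤
linear always. Overlapping windows are not truly independent; the seeded
Monte Carlo routine (vectorised NumPy, `default_rng`) quantifies the error,
which for hexamers stays within a percentage point or so of the binomial
values at these sizes. GC-biased or Markov null models are out of scope.

## Scanner

Input is one FASTA record or pasted viewer text; digits and whitespace are
stripped, case is normalised, and any residual non-ACGT symbol is an error
(ambiguity codes are rejected, not treated as wildcards — the tool's scope
is non-ambiguous hexamers). Scanning is a single pass with a dictionary of
site 6-mers; every occurrence is reported, overlapping ones included, with
1-based inclusive coordinates on the provided strand. Palindromic sites are
reported once per position; hybrid hits list every ordered pair that
regenerates the matched 6-mer.

## Planner

Junctions are placed greedily left to right. For a module starting at s the
next junction must leave a left module of `min_module..max_module` bp
(defaults 500/1300 — the wider-than-typical maximum reflects that published
MAC partitions include a 1287 bp module); candidates inside the window are
ranked by distance from the window midpoint, then palindromic before hybrid
(palindromic junctions need no corrective primer base), then enzyme name,
giving deterministic output. Bounded backtracking (a global candidate
budget of 5000) recovers from windows made unsatisfiable by a greedy early
choice; exhaustion raises `NoJunctionFound` naming the failing window.

Constraints checked at placement time:

* the enzyme that opens a module's left end must not cut elsewhere inside
  that module's amplicon (its two boundary sites excluded);
* the junction's left enzyme — which re-opens the growing assembly — must
  not cut anything assembled so far. In **strict sequential** mode (the
  default) that scan covers the whole assembled prefix, including earlier
  modules, earlier palindromic junction sites and a primer-added 5′ terminal
  site; in lenient mode only the adjacent module is scanned. Strict is the
  default because the simulator digests the entire growing assembly at each
  step, so only strict plans are guaranteed an empty safety report;
* terminal enzymes, when configured, must not cut anywhere inside the
  region (checked up front).

"Strictly inside a module" means any occurrence other than the junction
6-mers at the module's own termini; an occurrence of the right enzyme's
site at the incoming module's far boundary (a palindromic next junction
using the same enzyme) is tolerated and re-ligated transparently by the
simulator.

Primer additions: at a hybrid junction the left module's reverse primer
appends the left enzyme's final base and the right module's forward primer
prepends the right enzyme's first base, completing full recognition sites
whose digestion regenerates exactly the genomic 6-mer; palindromic
junctions add nothing; configured terminal enzymes contribute their full
6-mer (no extra clamp bases — clamp length is a PCR detail outside scope).

## Assembly simulation

A fragment is its top strand between top-strand cuts, with each end
annotated by cohesive-end sequence and polarity; under this convention
ligation of compatible ends is exact concatenation and digest→ligate
round-trips for both 5′ and 3′ overhangs (the latter needed for SacI
junctions). `simulate_assembly` replays the plan sequentially: digest the
growing assembly's right end with the junction's left enzyme, digest the
incoming amplicon's left end with the right enzyme, ligate; every cut other
than the intended one is recorded as a violation (with its target
coordinate; positions below the region start denote the primer-added 5′
terminus), the intended flanks are re-ligated, and assembly continues, so a
flagged plan still yields its product for inspection. Formed hybrid
junctions are checked to match no loaded enzyme's site on either strand.
The returned sequence has primer-added terminal sites stripped, so success
is byte-equality with the target region. `assembly_safety_check` derives
the same violation set statically from the plan and target, without
digestion; on any plan the two reports are equal, which the tests assert.

Linear DNA only; the vector backbone, partial digestion, dephosphorylation
and blunt ligation are not modelled, and the sequential left-to-right order
is an assumption, not a claim about any particular bench workflow.

## Synthetic data

`random_sequence` draws i.i.d. uniform bases from a seeded NumPy generator —
the same null model the statistics assume; real genomic composition bias,
repeats and methylation are not emulated, so passing tests demonstrate
algorithmic correctness, not guaranteed plannability of arbitrary genomic
input. `planted_target` embeds non-palindromic hybrid 6-mers at roughly
even intervals (default ~750 bp, ±60 bp jitter) and scrubs all native
recognition sites from the background by seeded single-base edits, so a
valid partition provably exists — these are the targets used for the
seamless-assembly property (planner success on unconstrained random
sequences depends on chance site layout and is exercised separately).
CHEF1 *surrogates* plant the published junction 6-mers at their printed
offsets on a scrubbed random background of the printed region length:
junction geometry, classification and assembly behaviour are testable
without the genomic residues, and tests assert only printed quantities.
Reconstructing the published upstream plan on its surrogate reproduces a
known conflict: the 5′ terminal enzyme (XhoI) recurs as a junction enzyme,
which strict checking flags while the assembly still completes seamlessly.

## Numerical and I/O choices

Coordinates are 1-based inclusive throughout, matching the published module
tables (module length = end − start + 1; hybrid junctions overlap 4 bp,
palindromic 6 bp). Tables are tab-delimited with headers; the site report
marks palindromic entries with a trailing asterisk; plan tables round-trip
(parse(format(plan)) reproduces modules and junctions). All stochastic
entry points take explicit integer seeds.
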