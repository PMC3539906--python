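# macplan

Modular assembly cloning (MAC) planner: map palindromic and **hybrid**
restriction sites on a target DNA sequence, partition a long fragment into
clonable 0.5–1.3 kb modules joined at cut-safe junctions, and verify the plan
by in-silico restriction digestion and sticky-end ligation.

## The problem

Cloning a genomic fragment of more than ~3–5 kb by direct PCR is often
impractical: long amplicons fail or accumulate point mutations faster than
clones can be screened. The MAC strategy instead divides the target into
consecutive 500–1300 bp modules, each PCR-amplified, cloned and sequence
verified individually with generic vector primers, then reassembled by
restriction–ligation. Because ligation of cohesive ends is essentially
error-free, the assembled product needs no re-sequencing.

Each module boundary is either

* a **natural palindromic site** — a 6-bp palindrome cut by one enzyme;
  adjacent modules overlap by the full 6 bp; or
* a **hybrid site** — two *compatible* 5′-cutting enzymes (isocaudomers,
  e.g. NcoI `C^CATGG` and PciI `A^CATGT`, both leaving `CATG`) cut the two
  neighbouring modules; ligating the ends regenerates the genomic 6-mer
  (NcoI + PciI → `CCATGT`), which is non-palindromic and cut by *neither*
  parent enzyme. Each primer supplies the single outer base completing its
  module's full recognition site, so the junction is seamless.

Under a uniform base model a given hexamer occurs once per 4⁶ = 4096 bp, so
single-enzyme sites are scarce (P(absent from 5 kb) = (1 − 4⁻⁶)⁴⁹⁹⁵ ≈ 29.5 %)
while the 4² × 4² = 256 hybrid 6-mers jointly recur every 16 bp — hybrid
junctions are what make the partition routinely solvable.

## Worked example

Map sites on a toy sequence (palindromic sites are starred, as in the
classic site-report convention):

```bash
$ printf '>t\nAAGGATCCTTAACCATGTTT\n' > toy.fasta
$ macplan map toy.fasta --out mapdir
# t
# 2 site occurrence(s)
3       GGATCC  BamHI *
13      CCATGT  NcoI+PciI
```

Plan and verify a partition of a synthetic 3.75 kb target:

```bash
$ macplan fixtures --kind planted --length 3750 --seed 3 --out tgt.fasta
$ macplan plan tgt.fasta --out plandir
module  start   end     length  five_re three_re
1       1       823     823             NcoI
2       820     1807    988     PciI    NheI
3       1804    2862    1059    SpeI    XbaI
4       2859    3750    892     NheI
$ macplan simulate tgt.fasta plandir/plan.tsv --out simdir
seamless: yes
OK: no unintended cuts.
```

Module 1 ends four bases into the genomic `CCATGT` hybrid at 820–825: its
reverse primer appends `G` (completing a true NcoI site `CCATGG`), module 2's
forward primer prepends `A` (completing PciI's `ACATGT`); after NcoI/PciI
digestion and ligation the genomic `CCATGT` is restored exactly — hence
"seamless: yes", confirmed byte-for-byte by the simulator. Consecutive
modules overlap 4 bp at hybrid junctions and 6 bp at palindromic ones.

The same machinery reproduces the published MAC partition of the two CHEF1
(Chinese hamster elongation factor 1 alpha) flanking fragments from their
printed module tables:

```python
>>> import macplan as mp
>>> up, down = mp.chef1_published_plan("upstream"), mp.chef1_published_plan("downstream")
>>> mp.classify_junctions(up), mp.classify_junctions(down)
((1, 3), (2, 3))        # 3 palindromic + 6 hybrid junctions in total
>>> [m.length for m in up.modules]
[586, 687, 779, 639, 1287]
```

Binomial site statistics:

```bash
$ macplan stats --lengths 500,1000,5000
length  p_no_site       p_single        p_multi
500     0.8862  0.1071  0.0067
1000    0.7843  0.1906  0.0251
5000    0.2953  0.3602  0.3444
```

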