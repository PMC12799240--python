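# gatescan

Discovery of protease-gated pro-nuclease defense loci from annotated
bacterial genomes.

Several unrelated prokaryotic antiphage systems — Hachiman, AVAST,
Lamassu, and DRT — have independently acquired the same two-gene cassette:
a metallo-β-lactamase (MBL)-fold nuclease encoded as a separate, typically
upstream gene, next to a trypsin-like protease fused to the N-terminus of
a core defense enzyme (HamA, the Avs STAND ATPase, LmuA, or a reverse
transcriptase).  The nuclease is a *gated proenzyme*: disordered
insertions block its active site until the partner protease cleaves
inside them — after conserved isoleucines in the trypsin systems, after
conserved glycines in caspase-partnered (*canu*) loci.  The hallmarks of
this coupling — residence in marker-rich defense contexts, nuclease–
protease coevolution, and active-site-proximal gating insertions — can be
turned into a search strategy for new protease-activated effector loci.
`gatescan` implements that strategy as a tested, reusable pipeline for
bioinformaticians studying antiviral defense systems.

## What it computes

For a set of annotated genomes (protein FASTA + GFF3) and per-family seed
alignments, the pipeline:

1. **scan** — builds position-specific scoring profiles
   (log₂-odds, `s(j,a) = log₂(((c_ja + τ·b_a)/(n_j + τ))/b_a)`) and scans
   every protein, with Gumbel-calibrated E-values
   (`E = N·e^{-(S-μ)/β}`, method-of-moments fit to a shuffled null);
2. **classify** — extracts the gene neighborhood of every nuclease hit
   and assigns a defense-system label from the locus grammar (trypsin
   fusion partner and context markers, or a standalone caspase upstream
   of the nuclease for *canu*), plus a defense-island score from extra
   defense/transposase markers nearby;
3. **coevo** — quantifies nuclease–protease coevolution: Poisson-corrected
   distances (`d = −ln(1−p)`), neighbor-joining trees, Robinson–Foulds
   distance, the Mantel correlation of patristic distances with a
   locus-pairing permutation null, and a Fitch label-parsimony transfer
   signal (changes in excess of `#labels − 1`);
4. **gate** — calls the gated-proenzyme signature by global affine-gap
   alignment against an ungated reference nuclease: insertion intervals
   from reference-side gap runs, active-site columns mapped into the
   candidate, conserved cleavage residues inside the insertions, and
   cut-site sequence logos (information `= log₂20 − H − 19/(2n·ln2)`);
5. **discover** — combines island score, gate score, marker evidence and
   Mantel congruence into a deterministic rank over candidate loci.

A first-class synthetic-data module generates genomes, gene families
(with joint nuclease–protease co-transfer events), and gated sequences
with known ground truth, so every stage is testable without external
databases.

## Worked example

Generate the default synthetic cohort (50 genomes; two implanted loci per
architecture across Hachiman/AVAST/Lamassu/DRT/*canu*; ten ungated decoy
nucleases) and run discovery:

```python
from gatescan.synthetic_data import generate_cohort
from gatescan.pipeline import discover_cohort, summarize

cohort = generate_cohort(seed=1)
report = discover_cohort(cohort)
print(summarize(report, top_n=5)[0])
```

```
system_label	n_loci	gated_fraction
Hachiman	2	1.000
AVAST	2	1.000
Lamassu	2	1.000
DRT	2	1.000
canu	2	1.000
unknown	10	0.000

top 5 candidates by rank score:
anchor_gene system_label  island_score  gate_score  rank_score
  g001_g019         canu             1         6.0    0.777778
  g026_g003         canu             1         6.0    0.777778
  g012_g017     Hachiman             1         6.0    0.750000
  g013_g016      Lamassu             1         6.0    0.750000
  g014_g015     Hachiman             1         6.0    0.750000
```

All ten implanted loci are recovered with their correct system label and
a full gate call (`gate_score` 6.0 = both insertions long, active-site
proximal, and cleavage-residue bearing); the ten decoys are labeled
`unknown` with zero gate score and rank below every implant.  The
coevolution block on the eight trypsin-partnered loci reports

```
nuclease~protease congruence: mantel_r=0.962 p=0.002 (999 permutations), RF=2
transfer signal: 6 label changes (vertical minimum 3, excess 3)
```

i.e. strongly congruent nuclease and protease trees (coevolution) with
three label changes beyond the vertical minimum (repeated, independent
acquisition across systems — here the three co-transfer events the
generator implanted).

The same pipeline runs from the shell:

```bash
gatescan synth --out cohort/ --seed 1
gatescan discover --genomes cohort/genomes --families cohort/families \
    --reference cohort/reference_nuclease.faa --out run/ --seed 1
gatescan summarize --report run/candidates.tsv
```

## Layout

- `src/gatescan/io_formats.py` — FASTA/GFF3/Newick I/O, genome data model,
  low-support branch collapsing
- `src/gatescan/profile_search.py` — profiles, scanning, E-value calibration
- `src/gatescan/neighborhood.py` — neighborhoods, fusion calls, motif checks,
  locus classification, island score
- `src/gatescan/coevolution.py` — distances, NJ, Robinson–Foulds, Mantel
  congruence, Fitch transfer signal
- `src/gatescan/gate_detection.py` — global alignment, insertion calling,
  active-site mapping, gate scoring, cleavage logos
- `src/gatescan/synthetic_data.py` — cohort/family/gate generators
- `src/gatescan/pipeline.py`, `src/gatescan/cli.py` — orchestration and CLI
- `src/gatescan/evaluation.py` — brute-force references and validation studies
- `docs/methods.md` — models, assumptions, parameter defaults, limitations
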