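# etrace

Evolutionary-trace site divergence between two ortholog groups, plus the
enzyme-kinetics quantification chain used to characterise the candidate
sites experimentally.

## The problem

When two subfamilies of a protein family share a fold and an active-site
nucleophile but differ in activity — the textbook case being human DJ-1
(an esterase and α-oxoaldehyde hydratase) versus its *E. coli* homolog
HchA (hydratase only) — the residues responsible for the functional
split can be predicted from sequence alone. Sites whose amino-acid usage
differs systematically *between* the subfamilies, while being conserved
*within* each, are candidate specificity-determining positions.

`etrace` scores every column *n* of a pooled multiple sequence alignment
with the symmetric Kullback–Leibler divergence between the two groups'
amino-acid compositions:

```
KL(n) = Σᵢ p(i) ln[ p(i)/q(i) ] + Σᵢ q(i) ln[ q(i)/p(i) ]        i = 1..20
```

where `p(i)` and `q(i)` are the probabilities of amino acid *i* at
column *n* in group A and group B. Compositions are regularised with an
additive pseudocount (default α = 0.5) so the divergence is finite;
gap-dominated columns are excluded by a per-group occupancy gate. Ranked
columns are reported with per-group conservation (modal-residue
frequency) and with the residue numbering of a reference sequence from
each group, so a hit can be read as, e.g., "A107 in the group-A
reference / H186 in the group-B reference".

The companion kinetics module quantifies enzyme activity from
spectrophotometric assay traces: initial velocities by linear regression
on the early phase (v₀ = |slope| × conversion factor), a nonlinear
Michaelis–Menten fit v = V·S/(Kₘ+S), and the derived constants
k_cat = V_max/[E]₀ and k_cat/Kₘ.

A synthetic-data module generates two-group alignments with *planted*
differentiation sites and assay traces with known (V_max, Kₘ), so every
stage of the pipeline can be validated against ground truth.

## Worked example

`examples/scan_divergence_sites.py` simulates 27 group-A and 24 group-B
orthologs over 300 columns with one planted site at column 42 (Ala at
82% in group A vs His at 99% in group B) and ranks all columns:

```
planted ground truth: column 42 (A in group A vs H in group B)

rank  column  refA        refB        KL
   1      42  A42 89%     H42 96%     5.2760
   2     188  F185 15%    T186 17%    1.2322
   3     257  H250 19%    D254 17%    1.2009
   4     144  V142 19%    F143 12%    1.1009
   5     232  F227 19%    K229 22%    1.0391
```

The planted column tops the ranking with a KL several-fold above the
background; `A42 89%` means the group-A reference carries Ala at its
42nd residue and 89% of group-A sequences agree (a finite-sample
realisation of the planted 82%). The runner-up sites are near-uniform
variable columns whose conservation (~15–20%) shows they are noise, not
signal.

`examples/fit_enzyme_kinetics.py` runs the kinetics chain on a simulated
esterase assay (V_max = 3.83×10⁻⁶ M/s, Kₘ = 4.76×10⁻³ M, 0.7 µM enzyme)
and prints:

```
Vmax    = 3.83e-06 M/s   (true 3.83e-06)
Km      = 0.00476 M     (true 0.00476)
kcat    = 5.47 /s    (= Vmax / [E]0)
kcat/Km = 1150 /s/M
```

i.e. the fit recovers the generating parameters exactly on noiseless
data, and kcat follows from the identity V_max/[E]₀.

## Command line

The same pipeline is exposed as an `etrace` executable:

```bash
etrace simulate-msa --planted 42:A:0.82:H:0.99 --seed 7 --outdir data/
etrace etrace --msa data/alignment.fasta --groups data/groups.tsv \
       --ref-a grpA_01 --ref-b grpB_01 --outdir scan/
etrace filter orthologs.fasta --max-identity 0.4 -o kept.fasta
etrace kinetics --traces-dir traces/ --outdir fits/
```

Inputs are plain FASTA (alignments), a two-column TSV of group labels,
and per-trace CSV + JSON sidecar files; outputs are TSV/JSON and are
byte-identical across reruns with the same inputs and parameters.

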