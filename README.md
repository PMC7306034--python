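# ndokit

A toolkit for PCR-based surveys of naphthalene 1,2-dioxygenase (NDO)
2Fe-2S reductase genes in contaminated-site microbial communities. It
covers the computational steps such a survey needs end to end:

- **CODEHOP-style primer design** — finding conserved amino-acid blocks in a
  protein alignment of the target gene family and assembling
  COnsensus-DEgenerate Hybrid Oligonucleotide Primers: a non-degenerate 5'
  *clamp* (most-frequent codon of each consensus flanking residue) fused to a
  short degenerate 3' *core* (fully degenerate reverse translation of a
  4-residue motif), under a degeneracy budget (≤ 64) and a conservation floor
  (≥ 80%).
- **In-silico PCR** — IUPAC set-membership matching of degenerate primers
  against sequenced templates, with an exact-match gate on the 3' core and a
  mismatch tolerance on the clamp, and amplicon prediction for convergent
  site pairs.
- **OPU clustering and phylogeny** — trimming and translating cloned
  amplicons, grouping them into operational protein units by
  complete-linkage clustering so that *every* within-OPU pair meets the
  protein-identity threshold (≥ 98%), and building neighbor-joining trees on
  Poisson-corrected distances *d* = −ln(1 − *p*) with bootstrap support.
- **In-silico T-RFLP** — AluI (AG^CT) digestion of 5'-labeled marker
  amplicons, terminal-restriction-fragment profiles, replicate consensus at
  a 0.5-bp confidence interval, and PCA of the community matrices.
- **Crystal-violet adherence assays** — the four-class cutoff scheme
  (non / weak / moderate / strong, with A_C = control mean + 3 SD) and
  summaries of isolate catalogues (taxonomy × degradation × gene detection).
- **Synthetic fixtures** — seeded generators that plant the structure each
  analysis assumes (conserved motifs, identity clusters, restriction sites,
  adherence classes), so everything is testable without downloads.

It is intended for microbiologists who design functional-gene primers for
ring-hydroxylating dioxygenases and analyse the resulting clone libraries
and community fingerprints.

## Worked example

Design a hybrid primer pair on a synthetic reductase-like family in which
the motifs CGTC and WRAY sit 246 alignment columns apart:

```python
from ndokit.synth import FamilySpec, gen_protein_family
from ndokit.codehop import design_primer_pairs

spec = FamilySpec(n_seqs=8, length=320, motifs={50: "CGTC", 296: "WRAY"},
                  conservation=0.5, motif_conservation=1.0, seed=3)
family = gen_protein_family(spec)
pairs = design_primer_pairs(family, extend_nt=2, product_range=(700, 800))
p = pairs[0]
print(f"forward  {p.forward}  ({p.forward.degeneracy}x)")
print(f"reverse  {p.reverse}  ({p.reverse.degeneracy}x)")
print(f"expected product: {p.expected_product_bp} bp")
```

prints

```
forward  TATTGGGGCGATCATGCGGTtgyggnacntg  (32x)
reverse  CTATCCCACCACTGCATCGGrtangcnckcca  (64x)
expected product: 790 bp
```

Upper case is the 20-nt consensus clamp (it depends on the family's flanking
residues and the codon-usage table); lower case is the degenerate core. The
forward core `tgyggnacntg` encodes the CGTC motif with its terminal wobble
trimmed (32 distinct oligos); the reverse core `rtangcnckcca` is the reverse
complement of the degenerate codons of WRAY (64 distinct oligos). The
expected product (~0.75–0.8 kb) is measured 5' end of the forward primer to
5' end of the reverse primer.

The same operations are available from the shell:

```sh
ndokit design family.fasta --extend-nt 2 --min-product 700 --max-product 800
ndokit pcr templates.fasta --forward ...tgyggnacntg --reverse ...rtangcnckcca
ndokit opu clones.fasta --threshold 0.98
ndokit summarize            # packaged 40-isolate catalogue
```

Every subcommand writes its resolved parameters to `run_config.json` next to
its outputs; identical configs and inputs give byte-identical outputs.

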