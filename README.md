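# quadrufold

Analysis toolkit for RNA G-quadruplex (rGQ) unfolding by arginine-rich
protein regions.

RNA sequences matching `G_x N_{1-7} G_x N_{1-7} G_x N_{1-7} G_x` can fold
into quadruplexes of stacked G-tetrads, whose stability grows with the
number of layers (bounded by the shortest G-tract, `min(x, 4)`). Arg-rich
low-complexity regions — the RS regions of SR/SR-related splicing factors
and designed repeats such as (RQ)_n or (RGG)_n — can unfold these
structures without ATP, provided they carry enough arginine (≥ 13 Arg for
the 3-layer ARPC2 quadruplex) and a net positive charge. `quadrufold`
implements the quantitative pipeline around that biology:

- **`gq_scan`** — G-tract finding, quadruplex motif enumeration, and
  2/3/≥4-layer classification of transcripts (FASTA in, BED-like TSV out).
- **`peptides`** — residue composition of Arg-rich peptides and the binary
  activity rule *active ⇔ arg_count ≥ 13 and net charge > 0*.
- **`fret`** — ensemble Cy3/Cy5 emission-spectrum normalization (donor
  maximum at 566 nm) and the unfolding fraction
  `(F₆₇₀,₀ − F₆₇₀,X) / F₆₇₀,₀` per protein dose.
- **`fp_binding`** — the one-site ligand-depletion (quadratic) model for
  fluorescence-polarization titrations,
  `F_p = F_min + (F_max − F_min)·[(P_T + L_T + K_D) − √((P_T + L_T + K_D)² − 4 P_T L_T)]/(2 L_T)`,
  fitted per replicate with K_D reported as mean ± SD.
- **`smfret`** — per-molecule FRET efficiencies `E = I_A/(I_A + γ I_D)`,
  histograms, two-Gaussian population mixtures by EM, and treatment time
  courses of the low-E population.
- **`contacts`** — geometric protein–RNA contact counting on multi-model
  PDB frames: H-bonds (≤ 3.5 Å, donor–H–acceptor ≥ 120°), salt bridges
  (N–O < 4 Å) and stacking (ring centroids < 4 Å, plane normals within
  30°), attributed to residue types and RNA moieties.
- **`synth`** — seeded generators for every input above, with planted
  ground truth, so the whole pipeline runs without downloads.

## Worked example

```python
>>> from quadrufold import scan_motifs, classify_transcript
>>> ARPC2 = "UGGGGGCUGGGCGGGGACCGGGU"   # quadruplex in the ARPC2 5'UTR
>>> best = max(scan_motifs(ARPC2), key=lambda m: m.layers)
>>> best.layers, [t.length for t in best.tracts], best.loop_lengths
(3, [5, 3, 4, 3], (2, 1, 3))
>>> classify_transcript(ARPC2)
3
```

The four G-tracts (5, 3, 4 and 3 G long, loops of 2, 1 and 3 nt) support
at most three stacked G-tetrads — a 3-layer quadruplex. Running
`python examples/peptide_panel.py` prints the designed-peptide panel:

```
     id  arg_count  net_charge  active                            reasons
 (RQ)10         10          10   False         insufficient Arg (10 < 13)
(RGG)13         13          13    True
 ...
 (RE)20         20           0   False charge neutralized (net charge +0)
    R30         30          30    True

minimum Arg count among active peptides: 13
```

i.e. ten arginines are not enough, twenty arginines neutralized by twenty
glutamates are not either, and the smallest active peptide carries 13 Arg.
Each script in `examples/` exercises one capability end to end
(`scan_transcripts`, `peptide_panel`, `unfolding_curve`, `fit_kd`,
`smfret_populations`, `contact_counting`).

A thin CLI wraps the same functions:

```sh
quadrufold scan --min-tract 2 --max-loop 7 in.fasta -o motifs.tsv
quadrufold simulate smfret --seed 1 -o syn/
quadrufold run demo.yaml
```

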