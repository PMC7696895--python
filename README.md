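# identmix

Combinatorial standard mixtures ("Ident-Mixes") for reliable identification
of isomeric metabolites in GC–MS and LC–MS.

## The problem

Most metabolites in the common databases share their molecular mass — often
their full sum formula — with other compounds, so neither exact mass nor a
mass spectrum alone identifies them: the aldohexoses (glucose, mannose,
galactose) score above 900/1000 against each other's electron-impact
spectra, and their retention indices sit within a couple of dozen RI units.
Worse, retention shifts between columns, vendors and batches, so a library
RI measured once cannot be trusted indefinitely.

The Ident-Mix strategy validates the retention of a whole panel of
authentic standards with only k extra injections per batch.  The n
standards are pooled into k mixtures (default k = 4, labels A–D) so that
each compound is present in **exactly two** of them.  Its pair of mixtures
— the *pair-code* — gives every compound a binary presence/absence
fingerprint across the k runs.  k mixtures support C(k,2) codes
(6 for k = 4, 10 for k = 5, 15 for k = 6), so up to that many mutually
similar compounds can be told apart purely by the *principle of exclusion*:
of the candidates for a peak, only the one whose code matches the peak's
across-mixture occurrence can be right.  Each mixture holds only 2/k of the
panel, and confirmed identifications refresh the library's retention
entries for identifying the samples of the same batch.

A confirmed identification requires, per library entry:

* a peak within the retention window (default ±10 RI units for GC,
  ±30 s for LC) in **both** code mixtures and **no other** mixture;
* the two supporting peaks consistent with each other (replicates of one
  analyte, default within 1 RI unit);
* intensity above a deliberately high floor (default 5% of the run's base
  peak — spiked standards always give strong signals);
* optionally, a reverse match factor ≥ 650 against the library spectrum.

Anything else is reported as `conflict` (contaminated pattern),
`not_found`, or `ambiguous` (two entries with the same code compete) —
machine-readable diagnostics rather than silent guesses.

## What is in the package

| module                 | contents                                                          |
| ---------------------- | ----------------------------------------------------------------- |
| `identmix.library`     | entry/spectrum model, the encoded-name codec (`Alanine_(3TMS)_MP_RI:1367_IDENT:B+C`), msp + TSV IO |
| `identmix.mixdesign`   | pair-code capacity, constrained code assignment (DISTINCT / DISJOINT / OVERLAP_ONE), design validation |
| `identmix.retention`   | van den Dool–Kratz retention indices from alkane ladders, RI↔RT, cross-setup shift reports and elution-order inversions |
| `identmix.spectra`     | Stein–Scott weighted-cosine match factors (forward and reverse, 0–1000), pairwise matrices |
| `identmix.pattern_id`  | presence detection, exclusion matching, isomer swapping, library retention updates |
| `identmix.isobars`     | isobar/isomer statistics over metabolite-database exports         |
| `identmix.synth`       | seeded synthetic batches and the bundled 13-sugar `table2` preset |
| `identmix.cli`         | the `identmix` command-line tool                                  |

## Worked example

Generate a zero-noise synthetic batch of the bundled sugar panel
(13 standards: pentoses, hexoses, sugar derivatives with their published
pair-codes) and identify it:

```sh
identmix simulate --preset table2 --seed 1 --out demo
identmix identify \
    --library demo/library.tsv --design demo/design.json \
    --ladder demo/ladder.tsv \
    --run A=demo/run_A.tsv --run B=demo/run_B.tsv \
    --run C=demo/run_C.tsv --run D=demo/run_D.tsv \
    --out demo/report.tsv --strict
```

which logs `identified 13 entries: {'confirmed': 13}` and writes a report
whose first lines are:

```
name                                        status     pattern  expected_ri  updated_ri
Xylose_(MeOX)(4TMS)_MP_RI:1651_IDENT:A+C    confirmed  A·C·     1651.0       1651.0
Ribose_(MeOX)(4TMS)_MP_RI:1672_IDENT:B+D    confirmed  ·B·D     1672.0       1672.0
...
Mannose_(MeOX)(5TMS)_MP_RI:1876_IDENT:A+D   confirmed  A··D     1876.0       1876.0
Galactose_(MeOX)(5TMS)_MP_RI:1880_IDENT:A+C confirmed  A·C·     1880.0       1880.0
Glucose_(MeOX)(5TMS)_MP_RI:1886_IDENT:B+D   confirmed  ·B·D     1886.0       1886.0
```

Every entry's observed pattern (`A·C·` = present in A and C, absent in B
and D) equals its pair-code, so all 13 are confirmed and their retention
indices are re-measured from the batch itself — even though the four
hexoses elute within 24 RI units of each other and qualify inside one
another's matching windows.  The same is doable from Python:

```python
from identmix import identify_batch
from identmix.synth import SimulationConfig, generate_truth, generate_peaklists

cfg = SimulationConfig(preset="table2", noise_sd=0.0, seed=1)
library, design = generate_truth(cfg)
runs, ladders = generate_peaklists(library, design, cfg)
identifications, updated_library = identify_batch(library, design, runs, ladders)
```

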