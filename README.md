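# aquascreen

Contamination-aware metagenomic pathogen detection for low-biomass
samples.

## The problem

In cell-poor specimens — amniotic fluid, CSF, plasma, reagent blanks —
nucleic acid introduced by extraction kits, buffers, and the lab
environment (the *kitome*) can dominate sequencing libraries, and a
single well-matched read is routinely a false positive caused by human
contamination of pathogen reference genomes or by read mis-assignment.
`aquascreen` implements a detection pipeline built for exactly this
regime: it cleans reads with a strict custom filter cascade, removes
human-like segments from reference databases, assigns reads through
tiered databases with a match score against residual human homology,
normalizes per-taxon abundance against pooled negative (water)
controls, and only reports an organism when a conservative set of
diagnostic criteria is met. A deterministic spike-in simulator lets
every stage — and the full experiment — run at desk scale with no
external data.

## The method in brief

Reads are quality-filtered (adapter and B-tail trimming; duplicate,
low-complexity, chastity, homopolymer-run, `N`, first-half-quality and
length filters), host-subtracted, and aligned records are accepted only
at ≥ 60 nt with ≤ 15% mismatches, ≤ 15% gaps, and ≤ 30% combined. The
viral database is interrogated first, then bacterial, then
fungal/protozoan. Each read receives a **match score**

    score = %id_organism/100 · L_organism − %id_human/100 · L_human

(the identical-base count of its organism alignment minus that of its
residual human alignment). Per-taxon abundance is normalized by the
**Water Normalization Score**

    WNS = (n_sample / N_sample) / (Σ n_water / Σ N_water)

with counts over species-concordant read pairs and totals over all
post-QC reads; pooling runs over all water controls. A taxon is called
**positive** only when all four diagnostic criteria hold:

1. both mates of a pair match the same species,
2. ≥ 3 mutually *discrete* linked pairs (< 50 bp pairwise overlap —
   evidence of independent template molecules),
3. match score > 0 for every contributing pair,
4. WNS > 1.0 (a taxon entirely absent from the water controls passes).

See `docs/methods.md` for the full model, parameter defaults, and the
simulator's assumptions.

## Worked example

Simulate a complete experiment — five water controls plus one sample
per spike level (200 / 1000 / 5000 genome copies of a test virus over a
shared kitome background) — and analyze it end to end:

```python
from aquascreen.simdata import SimConfig, run_spike_experiment
from aquascreen.pipeline import analyze_bundle

cfg = SimConfig(rng_seed=1)
bundle = run_spike_experiment(cfg)
results, calls = analyze_bundle(bundle)
for sample in bundle.sample_names:
    for c in calls[sample]:
        wns = "absent-in-water" if c.wns == float("inf") else f"{c.wns:.2f}"
        print(f"{sample:>10}  {c.taxon}  {c.verdict:<8}  pairs={c.n_concordant_pairs:<3} "
              f"discrete={c.n_discrete_pairs:<3} wns={wns}")
```

```
  spike200  B004  negative  pairs=1   discrete=1   wns=absent-in-water
  spike200  F001  negative  pairs=1   discrete=1   wns=4.92
  spike200  V001  negative  pairs=1   discrete=1   wns=absent-in-water
 spike1000  V001  positive  pairs=5   discrete=4   wns=absent-in-water
 spike5000  V001  positive  pairs=46  discrete=16  wns=absent-in-water
 spike5000  F001  negative  pairs=1   discrete=1   wns=4.87
```

The spiked virus `V001` is recovered at 1000 and 5000 genome copies
(5 and 46 concordant pairs, of which 4 and 16 are discrete) and missed
at 200 copies, where Poisson sampling left a single pair — the
marginal-detection regime. Kitome taxa (`B004`, `F001`) surface with a
single pair each and are rejected by the discreteness criterion even
when their WNS fluctuates above 1; this is the false-positive control
the criteria provide.

The same stages are available from the shell:

```sh
aquascreen simulate --seed 1 --out-dir fixtures/
aquascreen qc --in fixtures/spike5000_R1.fastq fixtures/spike5000_R2.fastq --out-prefix clean
aquascreen clean-db --refs db.fa --human-hits hits.tsv --out clean.fa --manifest manifest.tsv
aquascreen report --seed 1 --out calls.tsv
```

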