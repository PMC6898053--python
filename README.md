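# contactsr

**Structural relevance scoring of protein contact maps.**

Not every entry of a contact map carries the same amount of information.
Many contacts are redundant — implied by their neighbours and by chain
connectivity — while a few convey unique distance constraints without which
a structure cannot be reconstructed correctly. `contactsr` quantifies this
per contact: it is aimed at structural bioinformaticians who work with
contact-guided reconstruction, contact prediction quality assessment, or
the relationship between folding data and residue-level structure.

## The score

For a single chain with native Cα structure *S*<sub>native</sub>, the native
contact map *C*<sub>native</sub> contains all residue pairs with Cα distance
< 8 Å and sequence separation ≥ 6 (short-range 6–11, medium 12–23, long
> 23). The **structural relevance** (SR) of a contact *c* is measured by
toggling it inside sparse baseline subsets:

1. Sample *r* = 10 random subsets *C*<sub>baseline,*i*</sub> covering 30% of
   *C*<sub>native</sub> and reconstruct each; 30% coverage keeps the
   reconstruction near the fold/no-fold boundary, where a single contact has
   maximal leverage.
2. For each contact and each baseline, *toggle* the contact (remove it if
   present, add it if absent) and reconstruct again.
3. ΔRMSD<sub>*c*</sub> = RMSD<sub>baseline,*i*</sub> −
   RMSD<sub>toggle,*i*</sub> when *c* was added, and the negation when *c*
   was removed, so positive always means the contact helps.

SR(*c*) is the mean ΔRMSD<sub>*c*</sub> over the *r* toggles (a TM-score
analogue is tracked alongside); per-residue relevance is the mean — and,
separately, the sum — over a residue's incident contacts. The whole
procedure costs *r*·(|*C*<sub>native</sub>|+1) reconstructions.

Reconstruction itself is a self-contained distance-geometry engine:
contacts, chain connectivity and optional helix annotations are compiled
into per-pair distance bounds, triangle-smoothed, metrized, embedded by
classical MDS and refined against the bounds; the five lowest-energy models
of an ensemble are scored against the native by Kabsch RMSD and TM-score,
with mirror resolution (distances carry no handedness). The engine is an
injectable dependency, so the scoring loop can drive any backend with the
same signature.

Around the score, the package provides coverage sweeps, rational selection
strategies (random / most / least relevant, range and feature bins with
size-matched complements), non-native contact injection in 1% bins, and the
statistical layer (two-tailed Mann-Whitney U, notched-box summaries,
feature-vs-relevance trend tables).

## Worked example

Generate a synthetic two-segment test structure whose segments are bridged
by exactly one long-range contact — the only constraint on their relative
placement — and score every contact:

```sh
python -c "from contactsr import make_unique_contact_bundle, write_ca_pdb; \
           write_ca_pdb(make_unique_contact_bundle(14, seed=0).trace, 'bundle.pdb')"
contactsr distill --pdb bundle.pdb --chain A \
    --redundancy 3 --n-candidates 4 --top-k 3 --refine-steps 500 \
    --seed 11 --out sr_run/
sort -t$'\t' -k5 -gr sr_run/contact_sr.tsv | head -3
```

```
i   j   separation  range_class  sr_rmsd  sr_tm   std    n_removed  n_added
1   29  28          long         9.877    0.106   0.610  1          2
17  24  7           short        1.530    0.032   0.469  1          2
7   13  6           short        1.249    0.021   1.077  1          2
```

The planted bridging contact (1, 29) ranks first with an SR of 9.9 Å —
omitting it from a sparse subset costs almost 10 Å of reconstruction error
on average — while the redundant short-range contacts score an order of
magnitude lower. `residue_sr.tsv` carries the per-residue aggregates, and
every output directory includes a `manifest.json` recording version,
configuration, input hashes and seed.

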