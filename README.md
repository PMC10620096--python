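# capcensus

Quantitative census of autophagic proteome remodelling from multiplexed
(TMT) proteomics.

During nutrient stress, macroautophagy degrades parts of the proteome with
marked selectivity for membrane-bound organelles (Golgi, ER). Given total
proteome measurements of autophagy-proficient (WT) and autophagy-null
(e.g. *ATG7*⁻/⁻ or *FIP200*⁻/⁻) cells with and without starvation,
`capcensus` answers four questions for proteomics and cell-biology groups
studying selective autophagy:

1. **Which proteins behave like autophagic cargo?** Every protein's
   standardized abundance profile is compared against the consensus profile
   of known autophagy fluxers by root-mean-square error,

   RMSE = √( Σᵢ (predictedᵢ − observedᵢ)² / n_channels ),

   and the lowest-RMSE decile is called as *candidate autophagy proteins*
   (CAPs) — proteins depleted on starvation in WT and rescued in the KO.
2. **How many molecules does autophagy remove, and from where?** A
   TMT-adapted proteome ruler apportions each peptide's MS1 precursor area
   to the untreated-WT channels by reporter-ion share and converts summed
   protein signal to copies per cell via the histone anchor,
   copiesᵢ = signalᵢ · m_DNA·N_A / (Mᵢ · Σ_histones signal_h). Combined with
   the starvation fold change, this yields a per-compartment census of
   copies lost, split into CAP-attributable and other loss.
3. **Which proteins are candidate selective-autophagy receptors?** Turnover
   evidence (starvation- and genotype-dependent loss) and ATG8-proximity
   evidence (starvation-induced, LIR-dependent APEX2 labelling) are each
   converted to priorities, scaled-ranked per experiment, combined by
   minimum within each class, and summed into a composite rank.
4. **Which cargo depends on a given receptor?** Proteins are classified as
   stabilized by a knockout when KO log2FC − WT log2FC > 0.2.

A synthetic-data module generates experiments with planted clients,
genotype-independent (translation-suppressed) confounders, known fluxers,
histones and receptors, so every stage can be validated against a known
ground truth.

## Worked example

```python
import capcensus as cc

cfg = cc.SimulationConfig(n_proteins=2000, seed=7)
exp, ann, truth = cc.simulate_quant(cfg)

z = cc.zscore(cc.log2_transform(cc.channel_normalize(exp, method="sum")))
caller = cc.CapCaller(fraction=0.10).fit(z.values, ann["known_fluxer"], exp.design)
caps = caller.cap_set_
print(f"scored {caps.n_scored} proteins; called {len(caps.members)} CAPs "
      f"(RMSE <= {caps.rmse_threshold:.3f})")

enr = cc.enrichment(caps, caller.rmse_.index, ann, grouping="compartment")
print(enr.loc[["Golgi", "ER", "cytosol"]].round(3))
```

prints

```
scored 2000 proteins; called 200 CAPs (RMSE <= 0.719)
         n_cap  n_background  odds_ratio  p_value  q_value
term
Golgi       51            89      15.871      0.0      0.0
ER          71           136      14.691      0.0      0.0
cytosol     33           906       0.210      0.0      0.0
```

— 200 proteins (the lowest-RMSE decile) are called as CAPs, and the Golgi
and ER are strongly over-represented among them (odds ratios ~15–16), while
the cytosol is depleted, the selectivity signature the census is built to
expose. Continuing to the copy-number census:

```python
pep = cc.simulate_peptides(exp, truth, ann, seed=8)
sig = cc.apportion_ms1(pep, exp.channels, exp.channels_for("WT", "UT"))
copies = cc.ruler_copies(sig, ann, dna_mass_pg=6.5)
logged = cc.log2_transform(cc.channel_normalize(exp))
fc = cc.fold_changes(logged, ("WT", "starved", "UT"))["log2fc"]
summary = cc.compartment_census(cc.copy_loss(copies, fc), caps, ann,
                                split_golgi=True)
print(f"total CAP copies lost per cell: {summary.total_cap_loss:.3e}")
print(summary.table.loc["Golgi membrane", "cap_attributable_fraction"].round(3))
```

prints

```
total CAP copies lost per cell: 7.346e+07
0.979
```

— about 7.3 × 10⁷ protein copies per cell are lost from CAPs, and ~98% of
all Golgi-membrane copy loss is attributable to CAPs in this simulation
(where Golgi clients are planted as genuinely autophagic).

The same stages are available as a CLI:

```sh
census simulate --seed 1 --out-dir run/
census call-caps --quant run/quant.tsv --design run/design.tsv \
    --annotations run/annotations.tsv --out-dir run/
census ruler --peptides run/peptides.tsv --design run/design.tsv \
    --annotations run/annotations.tsv --out-dir run/
```

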