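# cocryscreen

Virtual screening and dissolution analytics for pharmaceutical
cocrystals, built around the discovery workflow for a cocrystal of
cilnidipine (CILP, a BCS class II calcium-channel blocker with aqueous
solubility near 30 ng/mL) with *p*-toluenesulfonamide (TSA).

The package is for formulation and solid-state scientists who want to

* rank candidate coformers for an API by **molecular complementarity**
  (shape/polarity descriptor similarity over conformer ensembles),
* combine externally computed supercooled-liquid mixing enthalpies into
  the **F_screen** ranking function,
* analyse **dissolution–supersaturation–precipitation (DSP)** profiles
  of a supersaturating cocrystal (supersaturation ratio, congruency,
  percent dissolved, solubility comparisons),
* generate seeded synthetic descriptor libraries and DSP profiles with
  known ground truth for validation.

## The scores

**Complementarity score.** For each conformer pair, five descriptors are
compared: the short axis *S*, the axis ratios *M*/*L* and *S*/*L* of a
box enclosing the molecular van der Waals volume, the dipole moment μ,
and the fraction of N and O atoms (FNO). With cutoffs δ_D calibrated on
known cocrystals,

```
C_score = |ΔM/L|/0.31 + |ΔS|/3.23 + |ΔS/L|/0.28 + |Δμ|/5.94 + |ΔFNO|/0.29
```

averaged over all (API conformer, coformer conformer) pairs — ten API
conformers, one (rigid) or three (flexible) coformer conformers by
default. Lower is better. The alternative "default settings" rule
declares PASS iff every |Δ_D| ≤ δ_D; the hit rate is the percentage of
conformer pairs passing.

**F_screen.** Given the excess enthalpy ΔH_mix of the supercooled 1:1
API–coformer liquid (an input, computed elsewhere) and rotatable-bond
counts n,

```
F_screen = ΔH_mix + a · (max(1, n_drug) + max(1, n_coformer))
```

with `a` a fit parameter (default 0, with a warning). Lower is better.

## Worked example

```python
>>> import cocryscreen as cs
>>> lib = cs.fixture_library()                      # 33 named molecules
>>> round(cs.molar_mass(lib["cilnidipine"]), 1)
492.5
>>> dose = cs.CocrystalDose(total_mass=10.8, mw_api=492.5,
...                         mw_coformer=171.2, stoichiometry=1.0)
>>> mmol, mg_api, mg_cof = cs.dose_composition(dose)
>>> round(mmol, 3), round(mg_api, 1), round(mg_cof, 1)
(0.016, 8.0, 2.8)
```

A 10.8 mg dose of the 1:1 cocrystal contains 0.016 mmol of formula
units, i.e. 8.0 mg of API and 2.8 mg of coformer. Dissolving it in
80 mL and reaching 0.3 μM API against a crystalline solubility of
4.6×10⁻² μM gives a supersaturation of
`cs.supersaturation_ratio(0.3, 0.046)` → **6.52**.

Screening the shipped fixture library against cilnidipine:

```python
>>> api = cs.embed_conformers(lib.pop("cilnidipine"), 10, seed=2025)
>>> cofs = [cs.embed_conformers(m, cs.default_conformer_count(m, "coformer"),
...                             seed=2025) for m in lib.values()]
>>> cs.screen_mc(api, cofs).to_frame().head(3)
   rank                       name  mean_c_score   hit_rate  pass_default
0     1       p-toluenesulfonamide      2.257323  20.000000          True
1     2  naphthalene-2-sulfonamide      2.318368  20.000000          True
2     3               posaconazole      2.430716  56.666667          True
```

The known cocrystal former (TSA) tops the 32-coformer ranking; the
naphthalene analogue used as a screening control sits beside it. The
same pipeline is available from the shell:

```sh
cocryscreen screen-mc --api api.smi --coformers coformers.smi --api-confs 10
cocryscreen screen-fscreen --mix mix.csv --a 0.0 --n-drug 10
cocryscreen simulate-dsp --regime fassif --seed 7 --out profile.csv
cocryscreen dissolution --profile profile.csv --dose 10.8 --volume 80 \
    --solubility 25.0
```

## Layout

| module | contents |
| --- | --- |
| `cocryscreen.molecules` | SMILES/SDF parsing, molar mass, rotatable bonds, seeded ETKDG conformer ensembles |
| `cocryscreen.descriptors` | vdW box axes, dipole moment, FNO, descriptor vectors |
| `cocryscreen.complementarity` | C_score, PASS/FAIL rule, hit rate, coformer ranking |
| `cocryscreen.fscreen` | F_screen combiner over mixing-enthalpy tables |
| `cocryscreen.dissolution` | unit bookkeeping, supersaturation, congruency, percent dissolved, Welch comparison |
| `cocryscreen.synthetic` | fixture molecule library, DSP simulator, synthetic screening sets |
| `cocryscreen.cli` | `cocryscreen` command-line interface |

See `docs/methods.md` for the modelling assumptions and numerical
choices.
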