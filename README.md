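# psfsim

Community-level plant–soil feedback (PSF) analysis and simulation for a
semiarid shrub-steppe system in which three native bunchgrasses
(*Pseudoroegneria spicata* PSSP, *Festuca idahoensis* FEID, *Koeleria
cristata* KOCR) and three short-lived non-natives (*Bromus tectorum* BRTE,
*Centaurea diffusa* CEDI, *Sisymbrium loeselii* SILO) form two distinct,
persistent communities on opposite sides of historical tillage boundaries.

The package asks whether soil legacies alone can explain that landscape
pattern.  It (i) emulates a two-phase common-garden experiment in which five
conditioned soil types (PSSP, BRTE, CEDI, SILO and a mixed soil) receive a
native and a non-native test community, (ii) reproduces the experiment's
statistics, (iii) converts plot cover into soil-specific growth rates, and
(iv) runs a discrete-time community growth model — with and without feedback —
over landscape scenarios to compare predicted against observed native/
non-native dominance.

## The model

Each species *i* grows from seed (ground-cover fraction *I* = 0.004) at a
per-step multiplicative rate specific to the soil it stands on.  Rates come
from final cover *F* attained over a 55-step growing season:

    r_is = (F_is / I)^(1/55)

Growth on mixed ground is additive in the soil proportions p_s:

    N_i(t+1) = N_i(t) · Σ_s p_s(t) · r_is

Cover is then capped: total cover cannot exceed the pot-level carrying
capacity (max of the two group capacities, each estimated as mean + 2 SD of
observed community cover), and each origin group's total cannot exceed its
own capacity; caps rescale proportionally, preserving relative abundance.
Soil proportions are refreshed from plant relative abundance once per season
— each soil type is produced by the species that cultivates it, with all
native soils attributed to the dominant native, PSSP.  The null model gives
every species the single rate it earned on its "self" soil, removing the
feedback while keeping everything else fixed.

Positive feedback here is mutual suppression: the native community grows
~52% less on CEDI-conditioned soil, and the non-native community ~55% less on
PSSP-conditioned soil, than on the remaining soils.

## Worked example

```python
import psfsim as ps

plots = ps.generate_experiment(ps.GeneratorConfig(rng_seed=1))
res = ps.soil_treatment_anova(plots, "native")
# native community: F_4,120 = 39.60, p = 4.1e-21
#    PSSP:  26.3%  a
#    BRTE:  26.2%  a
#    CEDI:  12.7%  b     <- suppressed on the dominant non-native's soil
#    SILO:  24.9%  a
#   Mixed:  26.3%  a

rates = ps.derive_rate_table(plots)
caps = ps.derive_capacities(plots)       # k_native = 0.375, k_nonnative = 0.496

survey = ps.generate_survey(rng_seed=2)
report = ps.run_comparison(ps.build_scenarios(), rates, caps, survey)
print(report.table.round(1))
```

```
            psf_native  psf_nonnative  null_native  null_nonnative  obs_native  obs_nonnative
distance_m
-50               18.7           31.0         14.6            35.0        10.0           29.6
-5                21.0           28.7         14.6            35.0        14.2           25.4
 5                31.7           17.9         14.6            35.0        36.9            6.8
 50               33.3           16.3         14.6            35.0        40.3            4.2
```

Reading the table: with feedback, predicted dominance flips across the
tillage boundary exactly as observed — non-natives win on the abandoned-field
side (−50/−5 m), natives win on the never-tilled side (+5/+50 m), a 4/4
rank-order agreement (`report.psf_agreement`).  Without feedback the
faster-growing non-natives are predicted to dominate everywhere (2/4
agreement), so the soil legacy, not growth rate alone, carries the landscape
pattern.

The same pipeline is scriptable from a shell: `psfsim generate`,
`psfsim stats experiment|survey`, `psfsim derive-rates`, `psfsim simulate`
and `psfsim scenario --figure fig.png` (see `psfsim --help`).

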