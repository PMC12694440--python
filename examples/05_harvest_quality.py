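"""Field harvest-quality metrics and multi-trial aggregation.

Rates are mass fractions of a harvest trial: integrity (intact buds in the
300 g quartered sample), loss (dropped but cut mass), leakage (uncut mass),
qualified (length within spec). Aggregation reports the mean and the
population (divide-by-n) standard deviation across trials.
"""

from teaprof import FieldTrial, field_metrics, productivity, summarize_trials

trials = [
    FieldTrial(w_total=300, w1_intact=245.1, w2_sample=900, w3_dropped=5.7,
               w4_uncut=8.3, w5_qualified=270.6, area_m2=22, time_h=0.0126, cut_width_m=1.1),
    FieldTrial(w_total=300, w1_intact=240.9, w2_sample=950, w3_dropped=5.2,
               w4_uncut=10.7, w5_qualified=273.9, area_m2=22, time_h=0.0126, cut_width_m=1.1),
    FieldTrial(w_total=300, w1_intact=231.6, w2_sample=920, w3_dropped=7.0,
               w4_uncut=10.4, w5_qualified=263.7, area_m2=22, time_h=0.0126, cut_width_m=1.1),
]

per_trial = [field_metrics(t) for t in trials]
for i, m in enumerate(per_trial, 1):
    print(f"trial {i}: " + "  ".join(f"{k}={v:.2f}" for k, v in m.items()))

for key in ("integrity_rate", "loss_rate", "leakage_rate", "qualified_rate"):
    s = summarize_trials([m[key] for m in per_trial])
    print(f"{key}: mean={s.mean:.2f}%  population sd={s.sd:.3f}")

print(f"overall productivity sum(A)/(sum(T)*B): {productivity(trials):.1f} m^2/(m*h)")
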