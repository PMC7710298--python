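"""Summarize simulated PDX caliper data: tumor volumes, T/C growth
inhibition at end of study, and modified-RECIST response calls per arm."""

from pxopipe import SimulationConfig, gen_pdx_growth, mrecist_call, relative_tgi

cfg = SimulationConfig(
    seed=11,
    planted_effect_sizes={"gemcitabine+paclitaxel": 0.15, "5FU+oxaliplatin": 0.9},
)
df = gen_pdx_growth(cfg)
control = df[df.arm == "control"]

print(f"{'arm':<26}{'T/C(d28)':>10}{'best%':>9}{'bestAvg%':>10}{'call':>6}")
for arm in cfg.planted_effect_sizes:
    treated = df[df.arm == arm]
    tc = relative_tgi(treated, control, day=28)
    call = mrecist_call(treated, model_id="Panc-sim", arm=arm)
    print(f"{arm:<26}{tc:>10.3f}{call.best_response:>9.1f}"
          f"{call.best_avg_response:>10.1f}{call.call:>6}")

print("\nT/C is treated-over-control relative growth (lower = stronger")
print("inhibition); best% / bestAvg% are the most negative percent volume")
print("changes from baseline driving the CR/PR/SD/PD call.")
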