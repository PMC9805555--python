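"""Leave-one-out evaluation: ensemble summary vs counting baseline.

The scenario where the ensemble pays off: few samples (N=3) and structured
noise — one sample systematically mis-reports state 1 as state 2 at 30% of
its state-1 bins.  The regression ensemble learns the genome-wide state
co-occurrence and partially decodes the mis-reporting; the per-bin counting
baseline cannot.
"""

from csrep import GeneratorConfig, leave_one_out, structured_noise_group

cfg = GeneratorConfig(S=5, G=5000, N=3, seed=11)
consensus, group = structured_noise_group(cfg, pair=(1, 2), cross=0.3, n_confused=1)

loo_ens = leave_one_out(group, method="csrep", seed=3)
loo_cnt = leave_one_out(group, method="base_count")

print("per-state mean leave-one-out AUROC (higher = better held-out prediction):")
print(f"{'state':>6} {'ensemble':>9} {'base_count':>11}")
e = loo_ens.mean_auroc_by_state()
c = loo_cnt.mean_auroc_by_state()
for s in e.index:
    marker = "  <- mis-reported state" if s == 1 else ""
    print(f"{s:>6} {e[s]:>9.4f} {c[s]:>11.4f}{marker}")
print(f"{'mean':>6} {loo_ens.mean_auroc():>9.4f} {loo_cnt.mean_auroc():>11.4f}")
print("\nthe ensemble's advantage concentrates on the state corrupted by "
      "structured noise, mirroring its behavior on real small-N groups.")
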