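"""Robustness of the organ pattern over a batch of seeded runs.

Repeats the wild-type simulation with different random seeds and
summarizes how often each sepal-petal-reproductive pattern occurs, and
how variable each organ class is (coefficient of variation).  A small
batch is used here so the script finishes in a few minutes; increase
``n_runs`` for tighter statistics.
"""

from florasim.experiments import ExperimentSpec, run_batch

spec = ExperimentSpec(preset="wildtype", n_runs=8, base_seed=100)
summary, reports, failures = run_batch(spec)

print(f"{summary.n_runs} runs, pattern frequencies:")
for pattern, count in sorted(
    summary.pattern_frequency.items(), key=lambda kv: -kv[1]
):
    print(f"  {'-'.join(map(str, pattern))}: {count}")
print()
print(f"{'class':14s} {'mean':>6s} {'sd':>6s} {'cv%':>6s}")
for cls in ("sepal", "petal", "reproductive"):
    print(
        f"{cls:14s} {summary.per_class_mean[cls]:6.2f} "
        f"{summary.per_class_sd[cls]:6.2f} "
        f"{summary.per_class_cv_percent[cls]:6.1f}"
    )
print()
print("The modal pattern reflects the four sepal positions laid down during")
print("the influx window; the later whorls vary more from seed to seed.")
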