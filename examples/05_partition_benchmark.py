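"""Fit the partition curve to a labelled all-vs-all benchmark.

Builds a small decoy set spanning several folds, aligns every pair, labels
pairs same/different fold from the topology strings, and fits the curve
r = a sqrt(n) / (1 + exp((bN - n + c)/d)) that best separates the classes
under s = 100(TP - 0.5 FP)/(TP + FN).  The scale a that puts the curve
through each point doubles as a ranking score.
"""

import foldbench as fb

form = fb.Form(2, 5, 2)
folds = fb.enumerate_folds(form, 2, 5)
chosen = folds[:: len(folds) // 4][:4]
ds = fb.generate_fixture_set(form, chosen, models_per_fold=3, noise=1.0, seed=2)

report = fb.run_benchmark(ds, box_min_n=40, box_max_r=9.0)
c = report.partition.curve
print(f"comparisons surviving the box filter: {len(report.comparison_records)}")
print(f"fitted curve: a={c.a:.2f} b={c.b:.2f} c={c.c:.1f} d={c.d:.1f} N={c.N:.0f}")
print(f"counts: TP={report.counts.TP} FP={report.counts.FP} "
      f"FN={report.counts.FN} TN={report.counts.TN}")
print(f"s = {report.s:.1f}   TP fraction enclosed = {report.partition.tp_fraction:.2f}")
print("discrimination (peak running rank metric (TP-FP)/(TP+FP+100) per key):")
for key, df in report.discrimination.items():
    print(f"  {key:10s} {df.rank_metric.max():+.3f}")
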