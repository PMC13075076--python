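"""Information transfer rate and paired scheme comparisons.

Shows the Wolpaw bit rate for accuracy/class-count combinations at one
5 s selection per trial, and a paired t test with Cohen's d comparing
two accuracy sequences, as used to contrast command schemes.
"""

import numpy as np

import tonguemi as tm
from tonguemi.evaluate import ITRParams

print("Wolpaw ITR at 12 selections/min (5 s imagery per selection):")
for n, p in [(2, 0.7619), (2, 1.0), (4, 0.65), (6, 0.55)]:
    itr = tm.information_transfer_rate(ITRParams(n, p, trial_time_s=5.0))
    print(f"  N={n}  P={p:6.2%}  ->  {itr:5.2f} bits/min")
print("ITR rewards both accuracy and command-set size; at chance it "
      "is exactly 0.")

rng = np.random.default_rng(0)
acc_a = rng.normal(76, 6, 20)   # e.g. per-subject accuracies, scheme A
acc_b = acc_a - rng.normal(1.2, 3.0, 20)  # scheme B slightly worse
cmp = tm.paired_comparison(acc_a, acc_b)
print(f"\npaired comparison (n={cmp.n}): mean diff "
      f"{cmp.mean_difference:+.2f} pts, t({cmp.df})={cmp.t_statistic:.2f},"
      f" p={cmp.p_value:.3f}, d={cmp.cohens_d:.2f}, "
      f"95% CI [{cmp.ci_low:.2f}, {cmp.ci_high:.2f}]")
print("Cohen's d here is the mean paired difference over the SD of the "
      "differences; the CI always contains the mean difference.")
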