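"""Why a decoupled MAE: background false positives can hide missed plants.

Constructs a one-image scenario where a model misses 3 true plants but
hallucinates 3 counts on background.  The plain MAE is 0 — the errors
cancel in the total — while the decoupled DMAE, which scores foreground and
background separately through the pseudo mask, reports the full 6 counts of
error.
"""

from badacount import basic_metrics, dmae

y_true_fg, y_true_bg = 10.0, 0.0
y_est_fg, y_est_bg = 7.0, 3.0  # 3 missed plants, 3 counts on weeds

mae, mse, mape, r2 = basic_metrics(
    [y_est_fg + y_est_bg, 12.0], [y_true_fg + y_true_bg, 11.0]
)
d = dmae(
    [(y_est_fg, y_est_bg), (11.5, 0.5)],
    [(y_true_fg, y_true_bg), (11.0, 0.0)],
)
print(f"totals: estimated {y_est_fg + y_est_bg:.0f}, true {y_true_fg + y_true_bg:.0f}")
print(f"MAE  = {mae:.2f}   (image 1 contributes 0: errors cancel)")
print(f"DMAE = {d:.2f}   (image 1 contributes 6: |7-10| + |3-0|)")
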