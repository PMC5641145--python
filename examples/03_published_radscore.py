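"""Score patients with the frozen published 8-coefficient Rad-score.

The model is a linear combination of eight selected radiomic features
(4 CET1-w + 4 T2-w) applied to raw feature values; higher scores indicate
higher predicted risk of progression within 3 years.
"""

from radsig import published_model, rad_score

model = published_model()
print(f"intercept: {model.intercept}")
for name, coef in model.coefficients.items():
    print(f"  {coef:+.10f} * {name}")

zeros = {name: 0.0 for name in model.coefficients}
print(f"\nall-zero feature vector  -> Rad-score = {rad_score(model, zeros):.10f}")

example = dict(zeros)
example["CET1-w_5_fos_median"] = 1.0
print(f"median feature set to 1  -> Rad-score = {rad_score(model, example):.10f}")
print("(the difference is exactly that feature's coefficient, 0.0330481732)")
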