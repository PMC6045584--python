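"""Fit 3PL dose-response curves and compute AUC / robust-Z scores.

Pools triplicate surviving fractions per (cell line, drug), fits
SF(c) = d / (1 + (c/e)^b), integrates the curve over the log-dose range
into an unscaled AUC (1 = no effect, 0 = complete kill) and a scaled
AUC that discounts activity already present at the lowest dose, then
standardises each drug column into robust Z scores. The HR-defective
line should surface with the most negative PARPi Z scores.
"""

import tempfile
from pathlib import Path

from chemoscreen import make_fixture_bundle, read_screen_datasets
from chemoscreen.pipeline import fit_and_score

tmp = Path(tempfile.mkdtemp())
paths = make_fixture_bundle(tmp, seed=7)
datasets = read_screen_datasets(paths["reads"], paths["layout"], paths["library"])

fits, auc_u, auc_s, auc_z = fit_and_score(datasets)

print("unscaled AUC (rows = cell lines):")
print(auc_u.round(3).to_string())
print("\nrobust Z of the unscaled AUC (negative = sensitive):")
print(auc_z.round(2).to_string())
print(
    "\nOS-HRD's PARPi AUC near 0.2 vs ~1.0 for the revertant means the\n"
    "drug killed most cells across the titration only in the HR-defective\n"
    "line; its robust Z near -14 (the panel's MAD is small because the\n"
    "other five lines barely respond) marks it as the outlier responder."
)
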