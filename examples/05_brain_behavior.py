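"""Link regional activity to behavior and quantify within-pair coordination.

CCA finds the behavior/brain axis pair with the strongest correlation;
Wilk's lambda tests which factors are real. Within-pair coordination is
the Pearson correlation of female vs male regional counts across mate
pairs — and partialing out the pair's ejaculation count shows how much of
it mating drives.
"""

import numpy as np
import pandas as pd

from fosmap import (
    cca,
    generate_dataset,
    pair_similarity,
    partial_pair_similarity,
)
from fosmap.simulate import coordination_config

data = generate_dataset(coordination_config(seed=1))
design = data["design"]
bond = data["truth"]["bonding_rois"]

X = data["behavior"].df
Y = data["counts"].df[bond].astype(float)
res = cca(X, Y)
print(f"CC1 canonical correlation r = {res.canonical_correlations[0]:.3f}, "
      f"Wilk's p = {res.wilks.loc['CC1', 'p']:.2e}")
top = res.loadings_x["CC1"].abs().idxmax()
print(f"behavior loading highest on CC1: {top} "
      f"(loading {res.loadings_x.loc[top, 'CC1']:+.3f})")

pair_of = {r.animal_id: r.pair_id for r in design}
ej = X["ejaculation"].groupby(pd.Series({a: pair_of[a] for a in X.index})).first()
raw = pair_similarity(data["counts"], design, bond)
part = partial_pair_similarity(data["counts"], design, bond, ej)
print(f"within-pair similarity (mean diagonal r over {raw.n_pairs} pairs): "
      f"{np.nanmean(np.diag(raw.r.to_numpy())):.3f}")
print(f"after partialing ejaculation counts:   "
      f"{np.nanmean(np.abs(np.diag(part.r.to_numpy()))):.3f}")
print("-> female and male brains activate in lockstep, and controlling for"
      " mating success abolishes the correlation.")
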