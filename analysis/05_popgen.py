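#!/usr/bin/env python
"""Genetic diversity and LD effective population size, per survey year.

Observed/expected heterozygosity and fixation index averaged over loci
(with SEs), and the bias-corrected LD-Ne with jackknife-over-individuals
confidence intervals, overall and per sampling year.  Writes
results/diversity.csv and results/ne.json.
"""

import json
import math
from pathlib import Path

import pandas as pd

from skatekin.io import read_genotypes
from skatekin.popgen import diversity, ld_ne

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm = read_genotypes(ROOT / "data" / "genotypes_qc.csv")
    metadata = pd.read_csv(ROOT / "data" / "metadata.csv")
    grouping = metadata.set_index("id")["year"]

    div = diversity(gm, grouping)
    div.to_csv(ROOT / "diversity.csv", index=False)
    print(div.round(4).to_string(index=False))

    out = {}
    for label, sub in [("overall", gm)] + [
            (str(y), gm.take_samples(gm.sample_index(
                metadata.loc[metadata["year"] == y, "id"])))
            for y in sorted(metadata["year"].unique())]:
        res = ld_ne(sub, crit_maf=0.05)
        out[label] = {"ne": res.ne, "ci": list(res.ci),
                      "mean_r2": res.mean_r2,
                      "harmonic_mean_s": res.harmonic_mean_s}
        ci = tuple("inf" if math.isinf(x) else round(x) for x in res.ci)
        ne = "inf" if math.isinf(res.ne) else round(res.ne)
        print(f"Ne[{label}]: {ne} (95% CI {ci[0]}-{ci[1]})")
    with open(ROOT / "ne.json", "w") as fh:
        json.dump(out, fh, indent=2, default=str)


if __name__ == "__main__":
    main()
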