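"""Are signatures stable within a season, and does the anesthetic matter?

ANOSIM on Gower dissimilarities plus NMDS ordination for (a) early- vs
late-season broods at the repeatedly-sampled sites and (b) anesthetic vs
lethal collection of the method-comparison broods.  Writes ANOSIM results
and ordination coordinates.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import shellfingerprint as sf
from shellfingerprint.io_preprocess import log_standardize, log_transform
from shellfingerprint.ordination import anosim, gower_dissimilarity, nmds
from shellfingerprint.pipeline import preprocess, validate_config

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
EPOCH_BOUNDARY = pd.Timestamp("2015-07-05")


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    broods, _ = sf.generate_paper_like_fixture()
    cfg = validate_config({"bootstrap": {"seed": SEED}, "ordination": {"seed": SEED},
                           "assignment": {"seed": SEED}, "clustering": {"seed": SEED}})
    _, sig_z, _, _ = preprocess(broods, cfg)
    results = {}

    dates = pd.to_datetime(sig_z.meta["date"])
    epoch = np.where(dates <= EPOCH_BOUNDARY, "early", "late")
    for site in ["NS-site1", "CS-site1"]:
        mask = (sig_z.meta["site"] == site).to_numpy()
        sub = sf.SignatureSet(sig_z.values[mask], sig_z.meta[mask],
                              sig_z.transform_state)
        d = gower_dissimilarity(sub)
        res = anosim(d, epoch[mask], n_perm=999, seed=SEED)
        nm = nmds(d, k=2, n_starts=25, seed=SEED)
        results[f"temporal:{site}"] = {
            "R": res.R, "p": res.p_value, "stress": nm.stress,
            "n_early": int((epoch[mask] == "early").sum()),
            "n_late": int((epoch[mask] == "late").sum())}
        print(f"{site}: early/late ANOSIM R = {res.R:.3f}, p = {res.p_value:.3f} "
              f"(NMDS stress {nm.stress:.3f})")

    mc = sf.generate_method_comparison_dataset()
    mc_z, _ = log_standardize(log_transform(sf.average_replicate_ablations(mc)))
    d = gower_dissimilarity(mc_z)
    res = anosim(d, mc_z.meta["method"].to_numpy(), n_perm=999, seed=SEED)
    nm = nmds(d, k=2, n_starts=25, seed=SEED)
    results["method_comparison"] = {"R": res.R, "p": res.p_value,
                                    "stress": nm.stress}
    print(f"anesthetic vs lethal: ANOSIM R = {res.R:.3f}, p = {res.p_value:.3f} "
          f"(NMDS stress {nm.stress:.3f})")
    coords = pd.DataFrame(nm.configuration, columns=["NMDS1", "NMDS2"],
                          index=mc_z.values.index)
    coords["method"] = mc_z.meta["method"]
    coords.to_csv(ROOT / "method_nmds_coordinates.csv")
    (ROOT / "ordination_results.json").write_text(json.dumps(results, indent=1))
    print(f"written to {ROOT}")


if __name__ == "__main__":
    main()
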