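#!/usr/bin/env python
"""Per-residue TG interaction profile on the toroid fixture.

Scores every (TG bead, protein bead) pair with the logistic kernel
2/(1+e^{0.5r}) and sums per residue; on the chamber-TG toroid the four
conserved inner-ring contact residues (Phe57, Ser61, Leu105, Ser109) should
rank in the top quantile.  Writes the profile and ranking under
results/interaction/.
"""

import argparse
import json
from pathlib import Path

from lipidlens.interaction import interaction_score, profile_peaks
from lipidlens.synthetic_data import gen_toroid


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/interaction"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fix = gen_toroid(n_tg=60, seed=args.seed)
    profile = interaction_score(fix.trajectory, fix.selection)
    ranked = profile_peaks(profile, ["Phe57", "Ser61", "Leu105", "Ser109"])
    ranked.to_csv(args.out / "profile.csv", index=False)

    print("top 6 residues by time-averaged score:")
    for row in ranked.head(6).itertuples():
        print(f"  {row.rank:2d}. {row.residue_name}{row.residue_id}  "
              f"s = {row.score:.4f}")
    flags = ranked.attrs["in_top_quantile"]
    print(f"conserved residues in top 25%: {flags}")

    with open(args.out / "peaks.json", "w") as fh:
        json.dump({"in_top_quantile": flags,
                   "kernel_scale_per_A": profile.kernel_scale}, fh, indent=2,
                  sort_keys=True)


if __name__ == "__main__":
    main()
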