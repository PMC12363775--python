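#!/usr/bin/env python
"""Generate the synthetic study systems and their ground-truth sidecars.

Writes, under scratch/synthetic/ (bulky regenerable data, kept out of the
tracked results): a two-regime Brownian trajectory (the
diffusion study condition: D_bulk = 1.1, D_trap = 0.2 Å²/ns, mirroring the
all-atom coefficients), a bound/unbound state series with KD_true = 0.5, a
planted-lens trajectory, and the C11 double-ring toroid fixture — each with
a YAML sidecar recording the truth that downstream analyses must recover.
"""

import argparse
from pathlib import Path

import yaml

from lipidlens.synthetic_data import (
    BrownianConfig,
    TwoStateConfig,
    brownian_ground_truth,
    gen_brownian_trap,
    gen_planted_lens,
    gen_toroid,
    gen_two_state,
)
from lipidlens.trajectory_io import write_columnar


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("scratch/synthetic"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    cfg = BrownianConfig(seed=args.seed, init_frac_trap=0.3)
    write_columnar(gen_brownian_trap(cfg), out / "trap.traj.txt")
    with open(out / "trap.truth.yaml", "w") as fh:
        yaml.safe_dump(brownian_ground_truth(cfg), fh)
    print(f"trap walk: {cfg.n_particles} particles × {cfg.n_frames} frames, "
          f"D_bulk={cfg.d_bulk}, D_trap={cfg.d_trap} Å²/ns")

    ts = TwoStateConfig(seed=args.seed, n_frames=100_000)
    series = gen_two_state(ts)
    (out / "two_state.csv").write_text(
        "time_ns,bound\n"
        + "\n".join(f"{t:.6g},{int(s)}" for t, s in zip(series.times, series.state))
        + "\n"
    )
    with open(out / "two_state.truth.yaml", "w") as fh:
        yaml.safe_dump({"kd_true": ts.kd_true, "tg_conc": ts.tg_conc}, fh)
    print(f"two-state chain: {ts.n_frames} frames, KD_true={ts.kd_true}")

    traj, _, truth = gen_planted_lens(seed=args.seed)
    write_columnar(traj, out / "lens.traj.txt")
    with open(out / "lens.truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh)
    print(f"planted lens: onset at frame {truth['onset_frame']}, "
          f"{truth['cluster_size']} molecules")

    fix = gen_toroid(n_tg=60, seed=args.seed)
    write_columnar(fix.trajectory, out / "toroid.traj.txt")
    with open(out / "toroid.truth.yaml", "w") as fh:
        yaml.safe_dump(
            {"chamber_annulus": list(fix.chamber_annulus),
             "n_protomers": fix.n_protomers}, fh,
        )
    print(f"toroid: C{fix.n_protomers}, chamber annulus "
          f"{fix.chamber_annulus[0]:.0f}–{fix.chamber_annulus[1]:.0f} Å, 60 TG")


if __name__ == "__main__":
    main()
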