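"""Profile each simulated stack: cells, outgrowth and alignment vs depth.

Runs the full screening pipeline on the stacks from 01_simulate_stacks.py
and writes one profile CSV per regime under results/profiles/, plus a
figure combining the three depth profiles.  The moderate-guidance regime
should echo the published shape: counts and alignment highest at the
substrate, alignment decaying toward the 33% isotropic floor with height.
"""

import json
from pathlib import Path

from groovescreen import RunConfig, profile_stack, read_stack, write_profile

ROOT = Path(__file__).resolve().parents[1] / "results"
STACKS = ROOT / "stacks"
OUT = ROOT / "profiles"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows_by_regime = {}
    for tif in sorted(STACKS.glob("*.tif")):
        cfg_sidecar = json.loads((STACKS / f"{tif.stem}_config.json").read_text())
        stack = read_stack(tif, cfg_sidecar["pixel_size_xy"], cfg_sidecar["z_step_um"])
        run = RunConfig(
            groove_angle_deg=cfg_sidecar["groove"]["angle_deg"],
            pixel_size_xy=cfg_sidecar["pixel_size_xy"],
            z_step_um=cfg_sidecar["z_step_um"],
        )
        metrics = profile_stack(stack, run)
        write_profile(metrics, OUT / f"{tif.stem}_profile.csv")
        rows_by_regime[tif.stem] = metrics
        print(f"{tif.stem}:")
        for m in metrics:
            align = "   n/a" if m.alignment_pct is None else f"{m.alignment_pct:5.1f}%"
            print(f"  z={m.z_um:5.2f} um  cells={m.n_cells:3d}  "
                  f"outgrowth={m.total_outgrowth_um:8.1f} um  aligned={align}")
    _plot(rows_by_regime)


def _plot(rows_by_regime) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping figure")
        return
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for name, rows in sorted(rows_by_regime.items()):
        z = [m.z_um for m in rows]
        axes[0].plot(z, [m.n_cells for m in rows], "o-", label=name)
        axes[1].plot(z, [m.total_outgrowth_um for m in rows], "o-", label=name)
        axes[2].plot(z, [m.alignment_pct for m in rows], "o-", label=name)
    axes[2].axhline(33.3, ls="--", c="gray", lw=1, label="isotropic 33%")
    for ax, ylab in zip(axes, ["number of cells", "total outgrowth (um)", "alignment (%)"]):
        ax.set_xlabel("distance from substrate (um)")
        ax.set_ylabel(ylab)
    axes[2].legend(fontsize=8)
    fig.tight_layout()
    dest = OUT / "depth_profiles.png"
    fig.savefig(dest, dpi=150)
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
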