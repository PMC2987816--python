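"""Multi-scale sliding-window scan of the block.

Slides every window size from 1 to the block's usable window count across
the cohort of 01_simulate_cohort.py, localises the global LR-p minimum,
and reports whether it recovers the planted 9-window peak.  Writes the
per-size minima and the peak call; the full per-placement profiles are
recomputable in seconds and are not stored.
"""

import argparse
import json
from pathlib import Path

from hsmscan.datamodel import Region
from hsmscan.io import read_genotypes, read_methylation_tracks, write_results
from hsmscan.scan import peak_localise, scan_block, scan_permutation


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--n-perm", type=int, default=10_000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-prefix", type=Path, default=Path("results/scan"))
    args = ap.parse_args()

    tracks = sorted((args.cohort_dir / "tracks").glob("*.tsv"))
    matrix = read_methylation_tracks(tracks)
    genotypes = read_genotypes(args.cohort_dir / "genotypes.tsv", {"rs8050136": ("C", "A")})
    dosages = genotypes.dosages_for("rs8050136", matrix.sample_ids)
    truth = json.loads((args.cohort_dir / "truth.json").read_text())

    grid = matrix.grid
    block = Region(grid.chrom, grid.start, grid.window_to_coords(grid.n_unmasked).end, "FTO")
    profiles = scan_block(matrix, dosages, block, sizes="all")
    call = peak_localise(profiles)
    write_results(call.per_w, Path(f"{args.out_prefix}_per_size_minima.tsv"))

    s, e = call.best_start_index, call.best_start_index + call.best_w - 1
    perm_p = scan_permutation(
        matrix, dosages, block, [call.best_w], n_perm=args.n_perm, seed=args.seed
    )[call.best_w][call.best_start_index - 1]
    payload = {
        "best_w": call.best_w,
        "best_unmasked_windows": [s, e],
        "best_interval": str(call.best_interval),
        "best_lr_p": call.best_lr_p,
        "best_kw_p": call.best_kw_p,
        "pointwise_perm_p": perm_p,
        "n_perm": args.n_perm,
        "true_interval_unmasked": truth["effect_interval_unmasked"],
    }
    Path(f"{args.out_prefix}_peak.json").write_text(json.dumps(payload, indent=1))

    lo, hi = truth["effect_interval_unmasked"]
    print(f"scanned {len(profiles)} window sizes over {grid.n_unmasked} usable windows")
    print(f"  global minimum: w = {call.best_w}, unmasked windows {s}-{e} "
          f"({call.best_interval}), LR p = {call.best_lr_p:.3g}, KW p = {call.best_kw_p:.3g}")
    print(f"  pointwise permutation p = {perm_p:.3g} ({args.n_perm} shuffles)")
    print(f"  planted peak windows {lo}-{hi}: "
          + ("recovered (overlap)" if s <= hi and e >= lo else "missed"))
    # the narrow-scale view: where does the 9-window scan localise?
    row9 = call.per_w[call.per_w["w"] == 9]
    if len(row9):
        s9 = int(row9["start_index"].iloc[0])
        print(f"  narrow scale (w = 9): best placement at unmasked windows "
              f"{s9}-{s9 + 8} (LR p = {row9['min_lr_p'].iloc[0]:.3g}); "
          + ("on the planted peak" if s9 <= hi and s9 + 8 >= lo else "off the planted peak"))
    print(f"written to {args.out_prefix}_per_size_minima.tsv and {args.out_prefix}_peak.json")


if __name__ == "__main__":
    main()
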