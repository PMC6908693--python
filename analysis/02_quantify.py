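"""Quantify the oxylipin peak table into per-litre and per-cell profiles.

Applies the internal-standard formula ng = area * 1000 / standard_area,
normalizes by filtered volume and by total diatom density, aggregates the
six analytes into precursor (HTrA/EPA/DHA) and oxidation (hydroxy acid /
epoxy-alcohol) classes, and labels every week low / medium / high by its
per-cell total (0-100 / 100-300 / >300 fg per diatom cell).
"""

import argparse
from pathlib import Path

from oxynet import io as oio, quant

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/synthetic"))
parser.add_argument("--out", type=Path, default=Path("results/profile"))
args = parser.parse_args()

abundance = oio.read_table(args.data / "abundance.csv", oio.ABUNDANCE_SCHEMA)
peaks = oio.read_table(args.data / "peaks.csv", oio.PEAKS_SCHEMA)
profile = quant.build_profile(peaks, abundance.sum(axis=0))

args.out.mkdir(parents=True, exist_ok=True)
oio.write_table(profile.ng_per_litre, args.out / "ng_per_litre.csv", "sample")
oio.write_table(profile.fg_per_cell, args.out / "fg_per_cell.csv", "sample")
oio.write_table(profile.class_fg_per_cell, args.out / "class_fg_per_cell.csv", "sample")
oio.write_table(
    profile.production_group.rename("group").to_frame(), args.out / "groups.csv", "sample"
)

total_l = profile.class_ng_per_litre["total"]
total_c = profile.class_fg_per_cell["total"]
print(f"total LOFAs: {total_l.min():.2f}-{total_l.max():.2f} ng/L, "
      f"{total_c.min():.1f}-{total_c.max():.1f} fg/cell")
print("production groups:", profile.production_group.value_counts().to_dict())
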