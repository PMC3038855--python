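"""One-off generator for the genome-model and synthetic cytoband fixtures.

Run from repo root: python scratch/gen_genome_fixtures.py
"""

from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "cnakit" / "data"

# hg18 (NCBI36) chromosome lengths, bp
HG18 = [
    ("1", 247_249_719), ("2", 242_951_149), ("3", 199_501_827),
    ("4", 191_273_063), ("5", 180_857_866), ("6", 170_899_992),
    ("7", 158_821_424), ("8", 146_274_826), ("9", 140_273_252),
    ("10", 135_374_737), ("11", 134_452_384), ("12", 132_349_534),
    ("13", 114_142_980), ("14", 106_368_585), ("15", 100_338_915),
    ("16", 88_827_254), ("17", 78_774_742), ("18", 76_117_153),
    ("19", 63_811_651), ("20", 62_435_964), ("21", 46_944_323),
    ("22", 49_691_432), ("X", 154_913_754), ("Y", 57_772_954),
]

# Approximate centromere midpoints (Mb) used to split arms.
CEN = {
    "1": 124.3, "2": 93.3, "3": 91.7, "4": 50.4, "5": 47.7, "6": 60.5,
    "7": 59.1, "8": 45.2, "9": 48.8, "10": 40.3, "11": 52.9, "12": 35.4,
    "13": 16.0, "14": 15.6, "15": 15.8, "16": 38.2, "17": 22.2, "18": 16.1,
    "19": 28.5, "20": 27.1, "21": 13.2, "22": 14.7, "X": 59.5, "Y": 11.3,
}

# Hand-placed band ends (Mb) for chromosomes where the cohort tables cite
# sub-bands; chr21 is placed so that 35.11-35.15 falls in q22.12.  All other
# chromosomes get a generic coarse banding.  The whole map is approximate and
# synthetic -- see the file header written below.
DETAILED = {
    "21": [
        ("p13", 2.9), ("p12", 6.3), ("p11.2", 9.8), ("p11.1", 13.2),
        ("q11.1", 14.3), ("q11.2", 16.3), ("q21.1", 24.0), ("q21.2", 27.0),
        ("q21.3", 31.5), ("q22.11", 35.0), ("q22.12", 36.4), ("q22.13", 37.5),
        ("q22.2", 39.7), ("q22.3", None),
    ],
    "7": [
        ("p22", 7.2), ("p21", 16.3), ("p15", 28.0), ("p14", 45.0),
        ("p12", 54.0), ("p11", 59.1), ("q11.2", 72.0), ("q21", 98.0),
        ("q22", 107.4), ("q31", 127.5), ("q32", 132.6), ("q33", 136.7),
        ("q34", 143.0), ("q35", 148.4), ("q36", None),
    ],
    "14": [
        ("p13", 5.0), ("p12", 9.0), ("p11", 15.6), ("q11.2", 23.6),
        ("q12", 32.0), ("q21", 46.8), ("q22", 56.0), ("q23", 62.0),
        ("q24", 73.0), ("q31", 84.0), ("q32.1", 95.0), ("q32.2", 102.0),
        ("q32.3", None),
    ],
}


def generic_bands(chrom: str, length_mb: float) -> list[tuple[str, float]]:
    cen = CEN[chrom]
    p_names = ["p15", "p13", "p11"]
    q_names = ["q11", "q21", "q23", "q25"]
    bands = []
    step = cen / len(p_names)
    for i, name in enumerate(p_names[:-1]):
        bands.append((name, round(step * (i + 1), 2)))
    bands.append((p_names[-1], cen))
    qlen = length_mb - cen
    step = qlen / len(q_names)
    for i, name in enumerate(q_names[:-1]):
        bands.append((name, round(cen + step * (i + 1), 2)))
    bands.append((q_names[-1], None))
    return bands


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    with open(DATA / "hg18.chrom.sizes", "w") as fh:
        for name, length in HG18:
            fh.write(f"{name}\t{length}\n")

    lines = [
        "# Synthetic approximate cytoband map (hg18-like), UCSC cytoBand "
        "format (0-based half-open).",
        "# Author-constructed: band boundaries are approximate and tile each "
        "chromosome; not the UCSC file.",
    ]
    for chrom, length in HG18:
        length_mb = length / 1e6
        spec = DETAILED.get(chrom) or generic_bands(chrom, length_mb)
        prev = 0
        for band, end_mb in spec:
            end = length if end_mb is None else int(round(end_mb * 1e6))
            assert end > prev, (chrom, band)
            stain = "gneg" if band[-1] in "13579" else "gpos50"
            lines.append(f"{chrom}\t{prev}\t{end}\t{band}\t{stain}")
            prev = end
        assert prev == length, chrom
    (DATA / "cytobands_synthetic.txt").write_text("\n".join(lines) + "\n")
    print("wrote", DATA / "hg18.chrom.sizes", "and cytobands_synthetic.txt")


if __name__ == "__main__":
    main()
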