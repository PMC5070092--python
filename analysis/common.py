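"""Shared study-design constants for the analysis drivers.

One simulated genome ("LG1", 1 Mb at this desk scale) carrying an
ancestral XY sex-determination region shared by two descendant species,
sequenced as 21-male / 22-female pools at ~35x — the design the package
emulates.  Scripts 01-06 read and write under results/.
"""

from pathlib import Path

from poolsex.simulate import SimConfig
from poolsex.windows import Region

RESULTS = Path("results")
SIM_DIR = RESULTS / "sim"

CHROM_LENGTHS = {"LG1": 1_000_000}
SD_REGION = ("LG1", 400_000, 600_000)  # 0-based half-open
SEED = 20161018

# fates of ancestral sex-patterned sites in the descendant pair
FATE_FRACTIONS = (0.5, 0.31, 0.19)  # conserved, switched, Y-replaced

SPECIES_A = "species_a"  # e.g. S. melanotheron-like: broad, gradual SD region
SPECIES_B = "species_b"  # e.g. O. niloticus-like


def sim_config(seed: int = SEED) -> SimConfig:
    return SimConfig(
        chrom_lengths=CHROM_LENGTHS,
        sd_region=SD_REGION,
        n_males=21,
        n_females=22,
        mean_coverage=35.0,
        sd_snp_rate=2e-3,        # ~400 sex-patterned sites in the 200 kb region
        background_snp_rate=1e-3,
        seed=seed,
    )


def sd_region() -> Region:
    chrom, start, end = SD_REGION
    return Region("sd_region", ((chrom, start, end),))


def rest_region() -> Region:
    return Region.complement(CHROM_LENGTHS, [sd_region()])
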