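"""Genome coordinate tables and the merged alteration variable catalogue.

Coordinates are GRCh37 (the array era this pipeline targets): chromosome arm
boundaries are taken from the UCSC cytoband acrocentric-gap annotation, and
the eight recurrent focal regions are standard GRCh37 gene spans padded by
100 kb.  Internally everything is 0-based half-open; the SEG files on disk
are 1-based inclusive and converted at the I/O boundary only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

#: Chromosomes whose p arm is a stalk/satellite: only the q arm is callable.
ACROCENTRIC = frozenset({13, 14, 15, 21, 22})

#: Odd-numbered chromosomes whose trisomies define hyperdiploidy (HD).
HD_CHROMOSOMES = frozenset({3, 5, 7, 9, 11, 15, 19, 21})

#: The five recurrent IgH translocation partners (FISH-typed, mutually exclusive).
TIHG_TYPES = ("t(4;14)", "t(6;14)", "t(11;14)", "t(14;16)", "t(14;20)")

#: t-IgH partners that deregulate CCND2 or MAF; with 1q&13+ they define t&1q&13+.
T1Q13_TRANSLOCATIONS = frozenset({"t(4;14)", "t(14;16)", "t(14;20)"})

# (chrom) -> (p_end, q_start, chrom_length); p runs [0, p_end), q [q_start, len).
# p_end/q_start flank the centromeric (acen) gap. Acrocentrics carry q only.
_GRCH37_ARMS: dict[int, tuple[int, int, int]] = {
    1: (121535434, 124535434, 249250621),
    2: (92326171, 95326171, 243199373),
    3: (90504854, 93504854, 198022430),
    4: (49660117, 52660117, 191154276),
    5: (46405641, 49405641, 180915260),
    6: (58830166, 61830166, 171115067),
    7: (58054331, 61054331, 159138663),
    8: (43838887, 46838887, 146364022),
    9: (47367679, 50367679, 141213431),
    10: (39254935, 42254935, 135534747),
    11: (51644205, 54644205, 135006516),
    12: (34856694, 37856694, 133851895),
    13: (16000000, 19000000, 115169878),
    14: (16100000, 19100000, 107349540),
    15: (17000000, 20000000, 102531392),
    16: (35335801, 38335801, 90354753),
    17: (22263006, 25263006, 81195210),
    18: (15460898, 18460898, 78077248),
    19: (24681782, 27681782, 59128983),
    20: (26369569, 29369569, 63025520),
    21: (11288129, 14288129, 48129895),
    22: (13000000, 16000000, 51304566),
}

# Focal regions: GRCh37 gene spans +/- 100 kb padding. A region name may span
# several rows when its genes are not contiguous (FAM46C vs CDKN2C/FAF1).
_FOCAL_ROWS = [
    ("TP53", 17, "p", 7_465_097, 7_690_856),
    ("RB1", 13, "q", 48_777_887, 49_156_122),
    ("MYC", 8, "q", 128_648_315, 128_853_680),
    ("CKS1B", 1, "q", 154_844_376, 155_048_701),
    ("ANP32E/MCL1", 1, "q", 150_090_717, 150_652_214),
    ("FAM46C/CDKN2C/FAF1", 1, "p", 50_805_101, 51_540_309),
    ("FAM46C/CDKN2C/FAF1", 1, "p", 118_048_556, 118_265_067),
    ("TRAF3", 14, "q", 103_140_210, 103_477_835),
    ("CYLD", 16, "q", 50_642_050, 50_901_935),
]

# The merged alteration catalogue exactly as the printed Methods list orders
# it: arm-level gains ("Amp"), arm-level losses ("Del"), then the two merged
# labels. Gains on the HD odd chromosomes have no standalone entries - they
# are consumed by the "HD" label - and acrocentric chromosomes expose q only.
CATALOGUE: tuple[str, ...] = (
    "Amp 10p", "Amp 10q", "Amp 12p", "Amp 12q", "Amp 13q", "Amp 14q",
    "Amp 16p", "Amp 16q", "Amp 17p", "Amp 17q", "Amp 18p", "Amp 18q",
    "Amp 1p", "Amp 1q", "Amp 20p", "Amp 20q", "Amp 22q", "Amp 2p",
    "Amp 2q", "Amp 4p", "Amp 4q", "Amp 6p", "Amp 6q", "Amp 8p", "Amp 8q",
    "Del 10p", "Del 10q", "Del 11p", "Del 11q", "Del 12p", "Del 12q",
    "Del 13q", "Del 14q", "Del 15q", "Del 16p", "Del 16q", "Del 17p",
    "Del 17q", "Del 18p", "Del 18q", "Del 19p", "Del 19q", "Del 1p",
    "Del 1q", "Del 20p", "Del 20q", "Del 21q", "Del 22q", "Del 2p",
    "Del 2q", "Del 3p", "Del 3q", "Del 4p", "Del 4q", "Del 5p", "Del 5q",
    "Del 6p", "Del 6q", "Del 7p", "Del 7q", "Del 8p", "Del 8q", "Del 9p",
    "Del 9q", "HD", "t-IgH",
)

MERGED_VARIABLES = ("HD", "t-IgH")
CNA_VARIABLES: tuple[str, ...] = tuple(v for v in CATALOGUE if v not in MERGED_VARIABLES)

_NAME_RE = re.compile(r"^(Amp|Del) (\d{1,2})([pq])$")


def variable_kind(name: str) -> str:
    """Classify a catalogue entry as arm_gain, arm_loss or merged."""
    if name in MERGED_VARIABLES:
        return "merged"
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unknown alteration variable {name!r}; "
                         f"catalogue entries are {CATALOGUE}")
    return "arm_gain" if m.group(1) == "Amp" else "arm_loss"


def parse_variable(name: str) -> tuple[str, int, str]:
    """Split any syntactically valid arm variable ("Amp 9p", "Del 13q") into
    (direction, chromosome, arm). Accepts odd-chromosome gains, which are
    legal arm events even though the catalogue merges them into HD."""
    m = _NAME_RE.match(name)
    if m is None or not 1 <= int(m.group(2)) <= 22:
        raise ValueError(f"unknown alteration variable {name!r}; "
                         f"catalogue entries are {CATALOGUE}")
    return ("gain" if m.group(1) == "Amp" else "loss", int(m.group(2)), m.group(3))


def variable_name(direction: str, chromosome: int, arm: str) -> str:
    prefix = "Amp" if direction == "gain" else "Del"
    return f"{prefix} {chromosome}{arm}"


@dataclass(frozen=True)
class ArmDefinition:
    chromosome: int
    arm: str  # "p" or "q"
    start: int  # 0-based half-open
    end: int
    acrocentric: bool

    @property
    def name(self) -> str:
        return f"{self.chromosome}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


def arm_table(build: str = "GRCh37") -> pd.DataFrame:
    """Chromosome arm coordinate table (autosomes only).

    Columns: chromosome, arm, start, end, acrocentric. Acrocentric
    chromosomes (13, 14, 15, 21, 22) expose only their q arm.
    """
    if build != "GRCh37":
        raise ValueError(f"no bundled arm table for build {build!r}; "
                         "supply a custom table instead")
    rows = []
    for chrom, (p_end, q_start, length) in _GRCH37_ARMS.items():
        acro = chrom in ACROCENTRIC
        if not acro:
            rows.append((chrom, "p", 0, p_end, False))
        rows.append((chrom, "q", q_start, length, acro))
    return pd.DataFrame(rows, columns=["chromosome", "arm", "start", "end", "acrocentric"])


def arm_definitions(arms: pd.DataFrame | None = None) -> list[ArmDefinition]:
    if arms is None:
        arms = arm_table()
    return [ArmDefinition(int(r.chromosome), str(r.arm), int(r.start), int(r.end),
                          bool(r.acrocentric))
            for r in arms.itertuples(index=False)]


def focal_regions(padding: int = 0) -> pd.DataFrame:
    """The eight recurrent focal regions (columns: name, chromosome, arm, start, end).

    The bundled coordinates already include 100 kb of padding around the gene
    spans; ``padding`` adds further symmetric padding in base pairs.
    """
    df = pd.DataFrame(_FOCAL_ROWS, columns=["name", "chromosome", "arm", "start", "end"])
    if padding:
        df["start"] = (df["start"] - padding).clip(lower=0)
        df["end"] = df["end"] + padding
    return df


def load_arm_table(path) -> pd.DataFrame:
    """Read a custom arm table TSV with the same columns as :func:`arm_table`."""
    df = pd.read_csv(path, sep="\t")
    required = {"chromosome", "arm", "start", "end", "acrocentric"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"arm table missing columns: {sorted(missing)}")
    return df


def load_focal_table(path) -> pd.DataFrame:
    """Read a custom focal-region TSV (columns as :func:`focal_regions`)."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "chromosome", "arm", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"focal table missing columns: {sorted(missing)}")
    return df
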