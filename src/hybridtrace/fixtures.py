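"""Packaged worked-example fixtures and their loaders.

The centerpiece is the dozen-SNP verified-SNP table (genomic position,
reference and consensus genotype, 1st/2nd-best base frequencies rendered
as ``count\\depth`` strings, the two donors' array genotypes — including
one missing "N/A" cell — and the per-gene log2 expression difference).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd

TABLE1_COLUMNS = [
    "Chromosome",
    "Position",
    "Gene",
    "Ref. Gen.",
    "Consensus Genome",
    "1st Best Base",
    "1st Best Freq.",
    "2nd Best Base",
    "2nd Best Freq.",
    "HEF19 Genome",
    "hFL24 Genome",
    "Expression dhFL24-HEF19",
]


def _data_path(name: str):
    return resources.files("hybridtrace.data").joinpath(name)


def load_table1(path=None) -> pd.DataFrame:
    """Load the packaged verified-SNP table (12 rows) or one written by the user.

    The "N/A" genotype cell is kept as a literal string, not parsed as
    missing — the selection code treats it explicitly.
    """
    src = path if path is not None else _data_path("table1.tsv")
    with resources.as_file(src) if path is None else _nullcontext(src) as p:
        df = pd.read_csv(p, sep="\t", dtype={"Chromosome": str}, keep_default_na=False)
    df["Position"] = df["Position"].astype(int)
    df["Expression dhFL24-HEF19"] = df["Expression dhFL24-HEF19"].astype(float)
    if list(df.columns) != TABLE1_COLUMNS:
        raise ValueError("unexpected fixture columns")
    return df


class _nullcontext:
    def __init__(self, v):
        self.v = v

    def __enter__(self):
        return self.v

    def __exit__(self, *exc):
        return False


def parse_freq(freq: str) -> Tuple[int, int]:
    """Parse a ``count\\depth`` frequency string, e.g. '53\\82' -> (53, 82)."""
    count, depth = str(freq).split("\\")
    return int(count), int(depth)


def table1_genotype_table(table1: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Re-shape the fixture into the donor genotype-table dialect.

    donor1 = HEF19, donor2 = hFL24; positions stay 1-based genomic.
    """
    df = load_table1() if table1 is None else table1
    out = pd.DataFrame(
        {
            "chromosome": df["Chromosome"].astype(str),
            "position": df["Position"].astype(int),
            "gene": df["Gene"],
            "ref_allele": df["Ref. Gen."],
            "donor1_genotype": df["HEF19 Genome"],
            "donor2_genotype": df["hFL24 Genome"],
        }
    )
    return out


def table1_expression_log2fc(table1: Optional[pd.DataFrame] = None) -> pd.Series:
    """Per-gene log2 expression difference (hFL-direction positive)."""
    df = load_table1() if table1 is None else table1
    return df.drop_duplicates("Gene").set_index("Gene")["Expression dhFL24-HEF19"]


def table1_consensus_table(table1: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Re-shape the fixture into the transcriptome consensus-table dialect."""
    df = load_table1() if table1 is None else table1
    first = df["1st Best Freq."].map(parse_freq)
    second = df["2nd Best Freq."].map(parse_freq)
    return pd.DataFrame(
        {
            "chromosome": df["Chromosome"].astype(str),
            "position": df["Position"].astype(int),
            "ref_allele": df["Ref. Gen."],
            "consensus": df["Consensus Genome"],
            "first_best_base": df["1st Best Base"],
            "first_best_count": [c for c, _ in first],
            "second_best_base": df["2nd Best Base"],
            "second_best_count": [c for c, _ in second],
            "depth": [d for _, d in first],
            "first_best_freq": df["1st Best Freq."],
            "second_best_freq": df["2nd Best Freq."],
        }
    )


def toy_exon_annotation(table1: Optional[pd.DataFrame] = None, margin: int = 100):
    """A toy exon annotation covering every fixture SNP (closed 1-based)."""
    from hybridtrace.select import ExonAnnotation

    df = load_table1() if table1 is None else table1
    intervals: Dict[str, list] = {}
    for _, r in df.iterrows():
        pos = int(r["Position"])
        intervals.setdefault(str(r["Chromosome"]), []).append(
            (max(1, pos - margin), pos + margin)
        )
    return ExonAnnotation(intervals)


def write_fixtures(outdir) -> Dict[str, Path]:
    """Write the packaged fixture set to a directory.

    Emits the verified-SNP table, a toy exon BED, the UP1/UP2 anchor
    primers as FASTA, and a demo simulation config; returns the paths.
    """
    import yaml

    from hybridtrace.readprep import DEFAULT_ANCHORS
    from hybridtrace.simulate import SimulationConfig

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    table1 = load_table1()
    paths["table1"] = outdir / "table1.tsv"
    table1.to_csv(paths["table1"], sep="\t", index=False)

    paths["exons"] = outdir / "exons.bed"
    toy_exon_annotation(table1).to_bed(paths["exons"])

    paths["anchors"] = outdir / "anchors.fasta"
    with open(paths["anchors"], "w") as fh:
        for spec in DEFAULT_ANCHORS:
            fh.write(f">{spec.name}\n{spec.primer}\n")

    paths["config"] = outdir / "demo_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(SimulationConfig().to_dict(), fh, sort_keys=False)
    return paths
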