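"""Readers, writers and validation for every external table the pipeline touches.

All tabular inputs are tab-separated text with a header row (gzip accepted).
Readers return :class:`pandas.DataFrame` objects with canonical column names so
downstream modules never deal with source-specific layouts:

``effects``
    one row per independently associated SNP (``snp_id, chrom, pos,
    risk_allele, tier, region_id``), where *tier* labels the statistical
    confidence of the association (GW = genome-wide significant, SR =
    statistically replicated, NR = non-replicated) and *region_id* groups
    effects that share an associated region.
``proxies``
    linkage-disequilibrium proxies (``lead_snp, proxy_snp, r2``).
``catalogue``
    SNP -> regulatory feature -> target gene evidence rows (``snp_id,
    feature_id, feature_type, reg_class, cell_raw, bucket, n_experiments,
    target_gene``). ``reg_class`` is one of PEX (promoter/enhancer/
    transcription-activating), ZQI (inert/quiescent) or R (repressive);
    ``bucket`` is the aggregated cell-type group.
``eqtl``
    expression-QTL records (``snp_id, target_gene, bucket, effect_sign``).

Cell-type bucketing collapses heterogeneous source cell labels into the
analysis groups (B, T, M, CNS, the T-helper subsets, and a lung control);
cancer cell lines map to EXCLUDED and are dropped at load time.
"""

from __future__ import annotations

import gzip
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TIERS = ("GW", "SR", "NR")
BUCKETS = ("B", "T", "M", "CNS", "Th1", "Th2", "Th17", "Treg", "L")
EXCLUDED = "EXCLUDED"
REG_CLASSES = ("PEX", "ZQI", "R")

EFFECT_COLUMNS = ["snp_id", "chrom", "pos", "risk_allele", "tier", "region_id"]
PROXY_COLUMNS = ["lead_snp", "proxy_snp", "r2"]
CATALOGUE_COLUMNS = [
    "snp_id",
    "feature_id",
    "feature_type",
    "reg_class",
    "cell_raw",
    "bucket",
    "n_experiments",
    "target_gene",
]
EQTL_COLUMNS = ["snp_id", "target_gene", "bucket", "effect_sign"]


class FormatError(ValueError):
    """A file does not have the expected layout (missing column, bad row)."""


class ValidationError(ValueError):
    """A file parsed but its content violates an invariant."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv(path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", compression="infer")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def normalize_chrom(chrom) -> str:
    """Strip a leading ``chr`` prefix; chromosome labels are plain strings."""
    s = str(chrom)
    return s[3:] if s.lower().startswith("chr") else s


# ---------------------------------------------------------------------------
# SNP effect lists and LD proxies


def read_effect_list(path, tier: str) -> pd.DataFrame:
    """Read one tier's SNP effect list.

    Parameters
    ----------
    path
        Tab-separated file with columns ``snp_id, chrom, pos, risk_allele,
        region_id`` (extra columns ignored).
    tier
        One of ``GW``, ``SR``, ``NR``; recorded on every row.

    Returns
    -------
    DataFrame with the canonical effect columns. Logs the effect count and
    the number of distinct associated regions.
    """
    if tier not in TIERS:
        raise ValueError(f"tier must be one of {TIERS}, got {tier!r}")
    df = _read_tsv(path, ["snp_id", "chrom", "pos", "risk_allele", "region_id"])
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"{path}: duplicate snp_id within tier {tier}: {sorted(set(dup))[:5]}"
        )
    if df["region_id"].isna().any():
        raise ValidationError(f"{path}: region_id missing for some rows")
    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"].astype(str),
            "chrom": df["chrom"].map(normalize_chrom),
            "pos": df["pos"].astype(int),
            "risk_allele": df["risk_allele"].astype(str),
            "tier": tier,
            "region_id": df["region_id"].astype(int),
        }
    )
    logger.info(
        "read_effect_list(%s): %d %s effects in %d regions",
        path,
        len(out),
        tier,
        out["region_id"].nunique(),
    )
    return out


def effect_summary(effects: pd.DataFrame) -> dict:
    """Bookkeeping counts: effects, distinct regions, multi-effect regions."""
    by_region = effects.groupby("region_id").size()
    return {
        "n_effects": int(len(effects)),
        "n_regions": int(by_region.size),
        "n_multi_effect_regions": int((by_region > 1).sum()),
    }


def read_ld_proxies(path) -> pd.DataFrame:
    df = _read_tsv(path, PROXY_COLUMNS)
    if ((df["r2"] < 0) | (df["r2"] > 1)).any():
        raise ValidationError(f"{path}: r2 outside [0, 1]")
    if df.duplicated(subset=["lead_snp", "proxy_snp"]).any():
        raise ValidationError(f"{path}: duplicate (lead, proxy) pairs")
    return df[PROXY_COLUMNS].astype({"lead_snp": str, "proxy_snp": str, "r2": float})


def expand_ld(
    effects: pd.DataFrame,
    proxies: pd.DataFrame | None,
    r2_min: float = 0.5,
) -> dict[int, set[str]]:
    """Expand each region's lead SNPs with their LD proxies at ``r2 >= r2_min``.

    Every lead counts as its own proxy (r2 = 1), so regions are non-empty at
    any threshold. Proxies referencing unknown leads are skipped with a
    logged count.
    """
    if not 0 < r2_min <= 1:
        raise ValueError(f"r2_min must be in (0, 1], got {r2_min}")
    lead_regions: dict[str, list[int]] = {}
    region_snps: dict[int, set[str]] = {}
    for snp, region in zip(effects["snp_id"], effects["region_id"]):
        lead_regions.setdefault(snp, []).append(int(region))
        region_snps.setdefault(int(region), set()).add(snp)
    n_unknown = 0
    n_added = 0
    if proxies is not None and len(proxies):
        kept = proxies[proxies["r2"] >= r2_min]
        for lead, proxy in zip(kept["lead_snp"], kept["proxy_snp"]):
            regions = lead_regions.get(lead)
            if regions is None:
                n_unknown += 1
                continue
            for region in regions:
                region_snps[region].add(proxy)
                n_added += 1
    if n_unknown:
        logger.warning("expand_ld: skipped %d proxies with unknown lead SNPs", n_unknown)
    logger.info(
        "expand_ld(r2_min=%g): %d regions, %d proxy assignments added",
        r2_min,
        len(region_snps),
        n_added,
    )
    return region_snps


# ---------------------------------------------------------------------------
# Config maps


def read_class_map(path) -> dict[str, str]:
    """Feature_type -> {PEX, ZQI, R} mapping from a YAML/JSON key-value file."""
    with _open_text(path) as fh:
        mapping = yaml.safe_load(fh)
    bad = {k: v for k, v in mapping.items() if v not in REG_CLASSES}
    if bad:
        raise ValidationError(f"{path}: classes must be in {REG_CLASSES}, got {bad}")
    return {str(k): str(v) for k, v in mapping.items()}


def default_class_map() -> dict[str, str]:
    """The packaged default feature_type -> class mapping (editable copy shipped
    as ``prenet/data/feature_classes.yaml``)."""
    text = resources.files("prenet").joinpath("data/feature_classes.yaml").read_text()
    return {str(k): str(v) for k, v in yaml.safe_load(text).items()}


def read_bucket_map(path) -> dict[str, str]:
    """cell_raw label -> bucket mapping from a YAML/JSON key-value file."""
    with _open_text(path) as fh:
        mapping = yaml.safe_load(fh)
    valid = set(BUCKETS) | {EXCLUDED}
    bad = {k: v for k, v in mapping.items() if v not in valid}
    if bad:
        raise ValidationError(f"{path}: buckets must be in {sorted(valid)}, got {bad}")
    return {str(k): str(v) for k, v in mapping.items()}


# ---------------------------------------------------------------------------
# Regulatory feature catalogue


def load_catalogue(
    path,
    class_map: Mapping[str, str] | None = None,
    bucket_map: Mapping[str, str] | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Load the SNP->feature->gene evidence table and apply class/bucket maps.

    Rows whose cell label buckets to EXCLUDED (cancer cell lines) are dropped
    with a logged count. With ``strict=True`` an unmapped feature_type or
    cell_raw raises; otherwise unmapped feature types fall back to ZQI (zero
    weight) and unmapped cells to EXCLUDED, each with a warning.
    """
    df = _read_tsv(
        path, ["snp_id", "feature_id", "feature_type", "cell_raw", "n_experiments", "target_gene"]
    )
    if class_map is None:
        class_map = default_class_map()
    n_exp = df["n_experiments"].astype(int)
    if (n_exp < 1).any():
        raise ValidationError(f"{path}: n_experiments must be >= 1")

    reg_class = df["feature_type"].map(class_map)
    unmapped_types = sorted(df.loc[reg_class.isna(), "feature_type"].unique())
    if unmapped_types:
        if strict:
            raise ValidationError(f"{path}: unmapped feature_type labels {unmapped_types}")
        logger.warning(
            "load_catalogue: %d feature_type labels unmapped, defaulting to ZQI: %s",
            len(unmapped_types),
            unmapped_types[:10],
        )
        reg_class = reg_class.fillna("ZQI")

    if bucket_map is not None:
        bucket = df["cell_raw"].map(bucket_map)
        unmapped_cells = sorted(df.loc[bucket.isna(), "cell_raw"].unique())
        if unmapped_cells:
            if strict:
                raise ValidationError(f"{path}: unmapped cell labels {unmapped_cells}")
            logger.warning(
                "load_catalogue: %d cell labels unmapped, bucketed to EXCLUDED: %s",
                len(unmapped_cells),
                unmapped_cells[:10],
            )
            bucket = bucket.fillna(EXCLUDED)
    elif "bucket" in df.columns:
        bucket = df["bucket"].astype(str)
    else:
        raise FormatError(f"{path}: no bucket column and no bucket_map supplied")

    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"].astype(str),
            "feature_id": df["feature_id"].astype(str),
            "feature_type": df["feature_type"].astype(str),
            "reg_class": reg_class.astype(str),
            "cell_raw": df["cell_raw"].astype(str),
            "bucket": bucket.astype(str),
            "n_experiments": n_exp,
            "target_gene": df["target_gene"].astype(str),
        }
    )
    n_excluded = int((out["bucket"] == EXCLUDED).sum())
    if n_excluded:
        logger.info("load_catalogue: dropped %d EXCLUDED-bucket rows", n_excluded)
    out = out[out["bucket"] != EXCLUDED].reset_index(drop=True)
    logger.info("load_catalogue(%s): %d rows kept", path, len(out))
    return out


def read_eqtl(path) -> pd.DataFrame:
    df = _read_tsv(path, EQTL_COLUMNS)
    sign = df["effect_sign"].astype(int)
    if (~sign.isin([1, -1])).any():
        raise ValidationError(f"{path}: effect_sign must be +1 or -1")
    return pd.DataFrame(
        {
            "snp_id": df["snp_id"].astype(str),
            "target_gene": df["target_gene"].astype(str),
            "bucket": df["bucket"].astype(str),
            "effect_sign": sign,
        }
    )


# ---------------------------------------------------------------------------
# Protein interactome


def load_ppi(path) -> nx.Graph:
    """Load an undirected protein-interaction edge list (two columns, optional
    header, gzip accepted). Self-loops are removed and duplicate edges are
    collapsed regardless of orientation."""
    graph = nx.Graph()
    header_tokens = {
        "source", "target", "node1", "node2", "gene1", "gene2",
        "protein1", "protein2", "a", "b", "from", "to",
    }
    n_self = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            u, v = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (u.lower() in header_tokens or v.lower() in header_tokens):
                continue
            if u == v:
                n_self += 1
                continue
            graph.add_edge(u, v)
    if n_self:
        logger.info("load_ppi: removed %d self-loops", n_self)
    logger.info(
        "load_ppi(%s): %d nodes, %d edges", path, graph.number_of_nodes(), graph.number_of_edges()
    )
    return graph


# ---------------------------------------------------------------------------
# Writers (tab-separated, round-trip safe)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_ppi(graph: nx.Graph, path) -> None:
    with open(path, "wt") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def write_mapping(mapping: Mapping[str, str], path) -> None:
    with open(path, "wt") as fh:
        yaml.safe_dump(dict(mapping), fh, sort_keys=True)
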