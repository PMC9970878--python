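"""Readers and writers for the text formats shared by all modules.

Abundance matrices are plain TSV with features in rows and a header row of
sample identifiers; empty cells or ``NA`` denote missing values. The
validated kinase-substrate prior follows the PhosphoSitePlus
``Kinase_Substrate_Dataset`` dialect (tab-delimited, optional banner lines
before the header). Interactomes and activity matrices round-trip through
TSV edge lists / tables. All text I/O is UTF-8.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("sphinks")

_SITE_RE = re.compile(r"^(?P<protein>[A-Za-z0-9.\-]+)_(?P<residue>[STY])(?P<position>\d+)$")
_RSD_RE = re.compile(r"^(?P<residue>[STY])(?P<position>\d+)$")


@dataclass(frozen=True, order=True)
class PhosphositeID:
    """A phosphorylated residue: gene symbol + S/T/Y + 1-based position."""

    protein: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.protein}_{self.residue}{self.position}"

    @classmethod
    def parse(cls, s: str) -> "PhosphositeID":
        m = _SITE_RE.match(s)
        if m is None:
            raise ValueError(f"not a canonical phosphosite id: {s!r}")
        return cls(m.group("protein").upper(), m.group("residue"), int(m.group("position")))


def parse_site(s: str) -> PhosphositeID:
    """Parse ``GENE_Rpos`` (e.g. ``EGFR_Y1068``) into a :class:`PhosphositeID`."""
    return PhosphositeID.parse(s)


@dataclass
class AbundanceMatrix:
    """Feature x sample log2 abundance matrix with NaN as the missing mask.

    ``data`` is a float DataFrame, rows = features (gene symbols or
    canonical phosphosite strings), columns = samples. ``scale`` is
    ``"raw"`` or ``"log2"``; ``normalized`` records whether quantile
    normalization has been applied.
    """

    data: pd.DataFrame
    scale: str = "log2"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        dup_f = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_f:
            raise ValueError(f"duplicate feature ids: {dup_f}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.scale, self.normalized)


@dataclass
class ValidatedInteractionSet:
    """Curated (kinase gene symbol, phosphosite) pairs — the positive prior."""

    pairs: frozenset[tuple[str, str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.pairs = frozenset(self.pairs)

    @property
    def kinases(self) -> set[str]:
        return {k for k, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs


@dataclass
class Interactome:
    """Per-kinase SOPS: thresholded, correlation-filtered substrate lists.

    ``edges`` is a DataFrame with columns kinase, phosphosite,
    sphinks_score, spearman_rho, validated (0/1). ``tau`` is the global
    score threshold that produced it.
    """

    edges: pd.DataFrame
    tau: float = float("nan")

    _COLS = ["kinase", "phosphosite", "sphinks_score", "spearman_rho", "validated"]

    def __post_init__(self) -> None:
        missing = [c for c in self._COLS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"interactome missing columns: {missing}")
        s = self.edges["sphinks_score"]
        if len(s) and ((s < 0) | (s > 1)).any():
            bad = self.edges.loc[(s < 0) | (s > 1)].iloc[0]
            raise ValueError(
                f"sphinks_score outside [0,1]: {bad['sphinks_score']} "
                f"for ({bad['kinase']}, {bad['phosphosite']})"
            )
        self.edges = self.edges.drop_duplicates(["kinase", "phosphosite"]).reset_index(drop=True)

    def sops(self, kinase: str) -> pd.DataFrame:
        return self.edges[self.edges["kinase"] == kinase].reset_index(drop=True)

    @property
    def kinases(self) -> list[str]:
        return sorted(self.edges["kinase"].unique())

    def sops_sizes(self) -> pd.Series:
        return self.edges.groupby("kinase").size()

    def __len__(self) -> int:
        return len(self.edges)


def _read_table_lines(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Split a TSV into header fields and data rows, checking raggedness."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: no data rows")
    header = lines[0].split("\t")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(fields)} fields, expected {len(header)})"
            )
        rows.append(fields)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return header, rows


def read_abundance_matrix(path: str | Path, scale: str = "raw") -> AbundanceMatrix:
    """Read a features-in-rows TSV abundance matrix.

    First column holds feature ids, header row holds sample ids; empty
    cells or ``NA`` are missing. Duplicated feature or sample ids raise,
    naming the offenders; ragged rows raise with the line number.
    """
    header, rows = _read_table_lines(path)
    sample_ids = header[1:]
    dup_s = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dup_s:
        raise ValueError(f"{path}: duplicate sample ids: {dup_s}")
    feature_ids = [r[0] for r in rows]
    dup_f = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
    if dup_f:
        raise ValueError(f"{path}: duplicate feature ids: {dup_f}")
    vals = np.full((len(rows), len(sample_ids)), np.nan)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r[1:]):
            c = cell.strip()
            if c not in ("", "NA", "nan", "NaN"):
                vals[i, j] = float(c)
    df = pd.DataFrame(vals, index=feature_ids, columns=sample_ids)
    return AbundanceMatrix(df, scale=scale, normalized=False)


def write_abundance_matrix(m: AbundanceMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", na_rep="NA", index_label="feature")


def read_validated_interactions(
    path: str | Path, organism_filter: str | None = None
) -> ValidatedInteractionSet:
    """Read a PhosphoSitePlus ``Kinase_Substrate_Dataset``-style prior.

    Banner/preamble lines before the header are skipped: the header is the
    first line whose first tab-field is ``GENE``. Pairs are assembled as
    (GENE, SUB_GENE + "_" + SUB_MOD_RSD); duplicates collapse. When
    ``organism_filter`` is given, rows are kept only if both KIN_ORGANISM
    and SUB_ORGANISM (where present) match it case-insensitively. Rows
    with malformed SUB_MOD_RSD are skipped; the skip count is logged.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    header_idx = None
    for i, ln in enumerate(lines):
        if ln.split("\t")[0].strip() == "GENE":
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"{path}: no header row starting with 'GENE' found")
    header = [h.strip() for h in lines[header_idx].split("\t")]
    col = {name: j for j, name in enumerate(header)}
    for required in ("GENE", "SUB_GENE", "SUB_MOD_RSD"):
        if required not in col:
            raise ValueError(f"{path}: required column {required} missing")
    pairs: set[tuple[str, str]] = set()
    skipped = 0
    for ln in lines[header_idx + 1 :]:
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < len(header):
            fields = fields + [""] * (len(header) - len(fields))
        if organism_filter is not None:
            keep = True
            for oc in ("KIN_ORGANISM", "SUB_ORGANISM"):
                if oc in col and fields[col[oc]].strip():
                    if fields[col[oc]].strip().lower() != organism_filter.lower():
                        keep = False
            if not keep:
                continue
        rsd = fields[col["SUB_MOD_RSD"]].strip()
        m = _RSD_RE.match(rsd)
        if m is None:
            skipped += 1
            continue
        kinase = fields[col["GENE"]].strip().upper()
        sub = fields[col["SUB_GENE"]].strip().upper()
        if not kinase or not sub:
            skipped += 1
            continue
        site = PhosphositeID(sub, m.group("residue"), int(m.group("position")))
        pairs.add((kinase, str(site)))
    if skipped:
        logger.warning("read_validated_interactions: skipped %d malformed rows", skipped)
    return ValidatedInteractionSet(frozenset(pairs), source_tag=str(path))


def write_interactome(net: Interactome, path: str | Path) -> None:
    """Write an interactome as a TSV edge list (scores to 6 decimals)."""
    df = net.edges.copy()
    df["sphinks_score"] = df["sphinks_score"].map(lambda v: f"{v:.6f}")
    df["spearman_rho"] = df["spearman_rho"].map(lambda v: f"{v:.6f}")
    df["validated"] = df["validated"].astype(int)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tau={net.tau:.6f}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_interactome(path: str | Path) -> Interactome:
    tau = float("nan")
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# tau="):
            tau = float(first.strip().split("=", 1)[1])
            body = fh.read()
        else:
            body = first + fh.read()
    from io import StringIO

    if body.strip().splitlines().__len__() <= 1:
        edges = pd.DataFrame(columns=Interactome._COLS)
    else:
        edges = pd.read_csv(StringIO(body), sep="\t")
        edges["validated"] = edges["validated"].astype(int)
    return Interactome(edges, tau=tau)


def read_sample_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample_id, label) into a Series."""
    header, rows = _read_table_lines(path)
    if len(header) < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, label)")
    ids = [r[0] for r in rows]
    dup = sorted({s for s in ids if ids.count(s) > 1})
    if dup:
        raise ValueError(f"{path}: duplicate sample ids: {dup}")
    return pd.Series([r[1] for r in rows], index=ids, name="subtype")


def write_sample_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("subtype").to_csv(path, sep="\t", index_label="sample_id")


def read_activity_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_activity_matrix(act: pd.DataFrame, path: str | Path) -> None:
    act.to_csv(path, sep="\t", index_label="kinase", float_format="%.6f")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene/protein signatures in GMT format (name, description, members...)."""
    sigs: dict[str, set[str]] = {}
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {ln[:50]!r}")
        sigs[fields[0]] = {f for f in fields[2:] if f.strip()}
    return sigs


def write_gmt(signatures: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in signatures.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")
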