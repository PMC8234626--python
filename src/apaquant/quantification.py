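"""Computing ψ (relative polyA-site usage) from transcript quantifications.

Each polyA site's abundance is the summed abundance of its member terminal
fragments: TPM in rnaseq mode, estimated read counts in 3pseq mode (3'-end
libraries sample one fragment per molecule, so length normalisation would
penalise long transcripts). Site abundance is positionally scaled,

    scaled_m = unscaled_m * m / (n - 1),

and the gene's usage statistic is psi = sum(scaled) / sum(unscaled), which is
0 for exclusive use of the most proximal site and 1 for exclusive use of the
most distal site. Genes whose summed abundance in a sample falls below the
expression threshold (default 5) get psi = NA in that sample.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneAPAModel, Mode

logger = logging.getLogger(__name__)

EXPRESSION_THRESHOLD = 5.0

QUANT_COLUMNS = ("Name", "Length", "EffectiveLength", "TPM", "NumReads")


class QuantTableError(ValueError):
    """Malformed per-sample quantification table."""


@dataclass(frozen=True)
class SiteExpression:
    """Abundance of one polyA site in one sample, before/after scaling."""

    gene_id: str
    m: int
    tpm_unscaled: float
    tpm_scaled: float


def read_quant_table(path: str | os.PathLike, sample_id: str) -> pd.DataFrame:
    """Read a tab-separated quantification table (salmon ``quant.sf`` layout).

    Requires columns Name, Length, EffectiveLength, TPM, NumReads. Returns a
    DataFrame indexed by transcript name with ``sample_id`` recorded in
    ``attrs``.

    Raises :class:`QuantTableError` naming the missing column, or the
    1-based file line of the first non-numeric abundance value.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise QuantTableError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    for col in ("Length", "EffectiveLength", "TPM", "NumReads"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise QuantTableError(
                f"{path}: non-numeric {col} value {df[col].iloc[row]!r} "
                f"at line {row + 2}"  # +1 header, +1 one-based
            )
        df[col] = values
    if df["Name"].duplicated().any():
        dup = df["Name"][df["Name"].duplicated()].iloc[0]
        raise QuantTableError(f"{path}: duplicate transcript name {dup!r}")
    df = df.set_index("Name")
    df.attrs["sample_id"] = sample_id
    return df


def site_expression(
    gene_model: GeneAPAModel,
    quant_table: pd.DataFrame,
    mode: Mode = "rnaseq",
) -> list[SiteExpression]:
    """Per-site summed abundance with positional scaling applied.

    rnaseq mode sums member-fragment TPM; 3pseq mode sums estimated read
    counts. Fragments absent from the table contribute zero (quantifiers
    drop duplicate or zero-length sequences); one warning is logged.
    """
    n = gene_model.n
    column = "TPM" if mode == "rnaseq" else "NumReads"
    abundance = quant_table[column]
    missing: list[str] = []
    out = []
    for site in gene_model.sites:
        total = 0.0
        for frag in site.member_fragments:
            if frag.transcript_id in abundance.index:
                total += float(abundance[frag.transcript_id])
            else:
                missing.append(frag.transcript_id)
        scaled = total * (site.m / (n - 1)) if n > 1 else 0.0
        out.append(
            SiteExpression(
                gene_id=gene_model.gene_id,
                m=site.m,
                tpm_unscaled=total,
                tpm_scaled=scaled,
            )
        )
    if missing:
        logger.warning(
            "gene %s: %d fragment(s) absent from quant table (%s); counted as 0",
            gene_model.gene_id,
            len(missing),
            ", ".join(missing[:5]),
        )
    return out


def compute_psi(
    site_expressions: Sequence[SiteExpression],
    expression_threshold: float = EXPRESSION_THRESHOLD,
) -> float:
    """psi = sum(scaled) / sum(unscaled) for one gene in one sample.

    Returns NaN when the gene has fewer than two sites or its summed
    abundance is below ``expression_threshold`` (insufficient evidence).
    """
    if len(site_expressions) < 2:
        return math.nan
    total = sum(s.tpm_unscaled for s in site_expressions)
    if total < expression_threshold or total <= 0:
        return math.nan
    return sum(s.tpm_scaled for s in site_expressions) / total


def build_psi_table(
    gene_models: Mapping[str, GeneAPAModel],
    quant_tables: Mapping[str, pd.DataFrame],
    mode: Mode = "rnaseq",
    expression_threshold: float = EXPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Assemble the gene x sample psi matrix.

    Rows are genes, columns are sample ids, values in [0, 1] or NaN. The
    per-gene structural class is carried in an ``apa_class`` column, and the
    mode/threshold provenance in ``attrs``.
    """
    sample_ids = list(quant_tables)
    records = {}
    for gene_id in sorted(gene_models):
        model = gene_models[gene_id]
        row = []
        for sample_id in sample_ids:
            exprs = site_expression(model, quant_tables[sample_id], mode=mode)
            row.append(compute_psi(exprs, expression_threshold))
        records[gene_id] = row
    table = pd.DataFrame.from_dict(records, orient="index", columns=sample_ids)
    table.index.name = "gene_id"
    table.insert(
        0,
        "apa_class",
        [gene_models[g].apa_class or "NA" for g in table.index],
    )
    table.attrs.update(mode=mode, expression_threshold=expression_threshold)
    return table


def write_psi_table(table: pd.DataFrame, out_tsv: str | os.PathLike) -> None:
    """Write the psi matrix as TSV; missing values are spelled ``NA``."""
    table.to_csv(out_tsv, sep="\t", na_rep="NA", float_format="%.6f")


def read_psi_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a psi TSV written by :func:`write_psi_table`."""
    table = pd.read_csv(path, sep="\t", index_col="gene_id", na_values=["NA"])
    return table
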