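"""Synthetic two-site APA benchmark: truth-tagged fixtures and caller scoring.

The generator emulates a two-condition, three-replicates-per-condition
experiment over genes that each have exactly two polyA sites. Per gene:

* overall expression is a Dirichlet(alpha = 1) draw over genes, scaled to
  TPM (so gene TPMs sum to one million and marginals are near-exponential);
* a direction label — positive, negative, or control — constrains the psi
  values drawn for its six samples. Positive genes require the smallest
  condition-B psi to exceed the largest condition-A psi by at least the
  effect margin (default 0.1); negative genes the mirror image; control
  genes require every pairwise psi difference, within and across conditions,
  to stay below the control bound (default 0.25). Values are rejection
  sampled from Uniform(0, 1) until the constraint holds;
* gene TPM is split between the proximal site (share 1 - psi) and distal
  site (share psi), then among a site's transcripts by a uniform random
  partition, and converted to target read counts as TPM x transcript length
  x a library-size scaling.

The fixture is emitted as plain text: a toy GFF3 annotation (a configurable
tandem-UTR : alternative-last-exon mix, both strands), per-sample
quantification tables whose TPM/NumReads encode the truth after count
rounding, a truth table, and a sample sheet. Everything derives from one
seed via independent substreams, so the structural mix can change without
perturbing the psi assignment.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

DIRECTIONS = ("positive", "negative", "control")


class SimulationError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Benchmark study conditions.

    Defaults are the benchmark's reference design: 5000 two-site genes, a
    quarter each shifted toward distal and proximal usage, half unchanged;
    three replicates per condition; 0.1 effect margin; 0.25 control bound;
    fifty million total reads.
    """

    n_genes: int = 5000
    n_positive: int = 1250
    n_negative: int = 1250
    n_control: int = 2500
    replicates: int = 3
    effect_margin: float = 0.1
    control_bound: float = 0.25
    seed: int = 0
    library_size: float = 50e6
    tutr_fraction: float = 0.5
    poisson_noise: bool = False
    max_rejection_draws: int = 100_000

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative + self.n_control != self.n_genes:
            raise SimulationError(
                "n_positive + n_negative + n_control must equal n_genes"
            )
        if not 0 < self.effect_margin:
            raise SimulationError("effect margin must be positive")
        if self.effect_margin >= 1:
            raise SimulationError(
                "effect margin >= 1 is infeasible for psi in [0, 1]"
            )
        if self.control_bound <= 0:
            raise SimulationError("control bound must be positive")
        if self.replicates < 2:
            raise SimulationError("at least two replicates per condition")
        if not 0 <= self.tutr_fraction <= 1:
            raise SimulationError("tutr_fraction must be in [0, 1]")

    def rngs(self) -> dict[str, np.random.Generator]:
        """Independent substreams, one per simulation stage."""
        seq = np.random.SeedSequence(self.seed)
        names = ("direction", "expression", "psi", "split", "structure", "noise")
        return {
            name: np.random.default_rng(child)
            for name, child in zip(names, seq.spawn(len(names)))
        }


@dataclass
class SimTruth:
    """Ground truth for one generated fixture."""

    direction: pd.Series  # gene -> positive/negative/control
    gene_tpm: pd.Series  # gene -> assigned TPM
    psi: pd.DataFrame  # gene x sample assigned psi
    structure: pd.Series  # gene -> TUTR/ALE
    transcript_tpm: pd.DataFrame  # transcript x sample assigned TPM
    target_counts: pd.DataFrame  # transcript x sample target read counts
    sample_conditions: pd.Series  # sample -> condition label


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def assign_expression(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Gene TPMs: one Dirichlet(1, ..., 1) draw scaled to a million."""
    return rng.dirichlet(np.ones(config.n_genes)) * 1e6


def _accept_positive(margin: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda c: c[..., 1, :].min(axis=-1) - c[..., 0, :].max(axis=-1) >= margin


def _accept_negative(margin: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda c: c[..., 0, :].min(axis=-1) - c[..., 1, :].max(axis=-1) >= margin


def _accept_control(bound: float) -> Callable[[np.ndarray], np.ndarray]:
    def accept(c: np.ndarray) -> np.ndarray:
        flat = c.reshape(*c.shape[:-2], -1)
        return flat.max(axis=-1) - flat.min(axis=-1) < bound

    return accept


def _rejection_sample(
    rng: np.random.Generator,
    n_genes: int,
    replicates: int,
    accept: Callable[[np.ndarray], np.ndarray],
    max_draws: int,
    batch: int = 64,
) -> np.ndarray:
    """Draw (n_genes, 2, replicates) uniforms, redrawing until accepted."""
    out = np.empty((n_genes, 2, replicates))
    remaining = np.arange(n_genes)
    drawn = 0
    while remaining.size:
        if drawn >= max_draws:
            raise SimulationError(
                f"psi rejection sampling exceeded {max_draws} draws per gene; "
                "constraints are too tight for uniform sampling"
            )
        cand = rng.uniform(size=(remaining.size, batch, 2, replicates))
        ok = accept(cand)
        hit = ok.any(axis=1)
        first = ok.argmax(axis=1)
        sel = remaining[hit]
        out[sel] = cand[hit, first[hit]]
        remaining = remaining[~hit]
        drawn += batch
    return out


def assign_psi(
    config: SimConfig,
    directions: Sequence[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-gene psi, shape (n_genes, 2 conditions, replicates).

    Rejection-samples Uniform(0, 1) values per gene until the gene's
    direction constraint holds (see module docstring).
    """
    directions = np.asarray(directions)
    psi = np.empty((len(directions), 2, config.replicates))
    accepts = {
        "positive": _accept_positive(config.effect_margin),
        "negative": _accept_negative(config.effect_margin),
        "control": _accept_control(config.control_bound),
    }
    for direction in DIRECTIONS:  # fixed order keeps the stream stable
        idx = np.flatnonzero(directions == direction)
        if idx.size == 0:
            continue
        psi[idx] = _rejection_sample(
            rng,
            idx.size,
            config.replicates,
            accepts[direction],
            config.max_rejection_draws,
        )
    return psi


def split_tpm(
    gene_tpm: float,
    psi: float,
    transcripts_per_site: Sequence[int] = (1, 1),
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Split a two-site gene's TPM so the realised psi equals ``psi``.

    The proximal site gets ``gene_tpm * (1 - psi)`` and the distal site
    ``gene_tpm * psi`` — the inversion of the two-site psi formula. Within a
    multi-transcript site the allotment is partitioned uniformly at random
    (a flat Dirichlet); single-transcript sites take the whole allotment.
    Returns one TPM array per site, proximal first.
    """
    if len(transcripts_per_site) != 2:
        raise SimulationError("two polyA sites expected")
    site_tpms = (gene_tpm * (1.0 - psi), gene_tpm * psi)
    out = []
    for k, site_tpm in zip(transcripts_per_site, site_tpms):
        if k == 1:
            out.append(np.array([site_tpm]))
        else:
            if rng is None:
                raise SimulationError("rng required for multi-transcript sites")
            out.append(site_tpm * rng.dirichlet(np.ones(k)))
    return out


def tpm_to_counts(
    tpm: np.ndarray | float,
    length: np.ndarray | float,
    scaling: float = 1.0,
) -> np.ndarray:
    """Target read count: round(TPM x transcript length x scaling)."""
    return np.round(np.asarray(tpm, dtype=float) * np.asarray(length, dtype=float) * scaling)


# ---------------------------------------------------------------------------
# Toy gene structures
# ---------------------------------------------------------------------------

_GENE_SPAN = 7000
# exon layouts relative to the gene start, plus strand; minus-strand genes
# mirror these within the 0..5199 window
_LAYOUTS = {
    "TUTR": {
        "prox": ((0, 199), (1000, 2199)),
        "dist": ((0, 199), (1000, 3199)),
    },
    "ALE": {
        "prox": ((0, 199), (1000, 2199)),
        "dist": ((0, 199), (4000, 5199)),
    },
}
_MIRROR_MAX = 5199


def _gene_layout(index: int, structure: str) -> dict:
    """Coordinates for gene ``index``: alternating strand, mirrored on minus."""
    start = 1 + index * _GENE_SPAN
    strand = "+" if index % 2 == 0 else "-"
    exons = {}
    for role, rel in _LAYOUTS[structure].items():
        if strand == "+":
            abs_exons = [(start + a, start + b) for a, b in rel]
        else:
            abs_exons = sorted(
                (start + _MIRROR_MAX - b, start + _MIRROR_MAX - a) for a, b in rel
            )
        exons[role] = abs_exons
    return {"start": start, "strand": strand, "exons": exons}


def _transcript_length(exons: Sequence[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in exons)


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------


def _write_gff3(genes: pd.Index, structures: pd.Series, path: Path) -> None:
    lines = ["##gff-version 3"]
    for i, gene_id in enumerate(genes):
        layout = _gene_layout(i, structures[gene_id])
        strand = layout["strand"]
        all_exons = [e for role in ("prox", "dist") for e in layout["exons"][role]]
        gstart = min(s for s, _ in all_exons)
        gend = max(e for _, e in all_exons)
        lines.append(
            f"chrS\tsim\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
            f"ID={gene_id};gene_type=protein_coding"
        )
        for role in ("prox", "dist"):
            tx_id = f"{gene_id}.{role}"
            exons = layout["exons"][role]
            tstart = min(s for s, _ in exons)
            tend = max(e for _, e in exons)
            lines.append(
                f"chrS\tsim\ttranscript\t{tstart}\t{tend}\t.\t{strand}\t.\t"
                f"ID={tx_id};Parent={gene_id};transcript_type=protein_coding"
            )
            for j, (s, e) in enumerate(exons, 1):
                lines.append(
                    f"chrS\tsim\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID={tx_id}.exon{j};Parent={tx_id}"
                )
    path.write_text("\n".join(lines) + "\n")


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw the full ground truth for one fixture (no files written)."""
    rngs = config.rngs()
    genes = pd.Index(
        [f"gene{i:05d}" for i in range(config.n_genes)], name="gene_id"
    )

    labels = np.repeat(
        DIRECTIONS, (config.n_positive, config.n_negative, config.n_control)
    )
    direction = pd.Series(
        rngs["direction"].permutation(labels), index=genes, name="direction"
    )
    gene_tpm = pd.Series(
        assign_expression(config, rngs["expression"]), index=genes, name="gene_tpm"
    )
    psi = assign_psi(config, direction.to_numpy(), rngs["psi"])

    structure = pd.Series(
        np.where(
            rngs["structure"].uniform(size=config.n_genes) < config.tutr_fraction,
            "TUTR",
            "ALE",
        ),
        index=genes,
        name="structure",
    )

    samples = [
        f"sample{cond}_rep{r + 1}"
        for cond in ("A", "B")
        for r in range(config.replicates)
    ]
    conditions = pd.Series(
        ["A"] * config.replicates + ["B"] * config.replicates,
        index=samples,
        name="condition",
    )
    psi_table = pd.DataFrame(
        psi.reshape(config.n_genes, -1), index=genes, columns=samples
    )

    # per-transcript TPM (one transcript per site in the emitted fixture)
    tx_index = pd.Index(
        [f"{g}.{role}" for g in genes for role in ("prox", "dist")],
        name="transcript_id",
    )
    tpm = np.empty((len(tx_index), len(samples)))
    gvals = gene_tpm.to_numpy()
    for j in range(len(samples)):
        p = psi_table.iloc[:, j].to_numpy()
        tpm[0::2, j] = gvals * (1.0 - p)  # proximal
        tpm[1::2, j] = gvals * p  # distal
    transcript_tpm = pd.DataFrame(tpm, index=tx_index, columns=samples)

    lengths = np.array(
        [
            _transcript_length(
                _gene_layout(i, structure.iloc[i])["exons"][role]
            )
            for i in range(config.n_genes)
            for role in ("prox", "dist")
        ],
        dtype=float,
    )
    tpm_length = transcript_tpm.mul(lengths, axis=0)
    scaling = config.library_size / tpm_length.sum(axis=0)
    counts = pd.DataFrame(
        {
            s: tpm_to_counts(transcript_tpm[s], lengths, scaling[s])
            for s in samples
        },
        index=tx_index,
    )
    if config.poisson_noise:
        counts = pd.DataFrame(
            rngs["noise"].poisson(counts.to_numpy()).astype(float),
            index=counts.index,
            columns=counts.columns,
        )

    return SimTruth(
        direction=direction,
        gene_tpm=gene_tpm,
        psi=psi_table,
        structure=structure,
        transcript_tpm=transcript_tpm,
        target_counts=counts,
        sample_conditions=conditions,
    )


def emit_fixture(config: SimConfig, outdir: str | os.PathLike) -> SimTruth:
    """Write the benchmark fixture to ``outdir`` and return its truth.

    Files: ``annotation.gff3``, one ``<sample>.quant.tsv`` per sample in the
    standard quant-table layout, ``truth.tsv``, ``samplesheet.tsv``. The
    emitted TPM column is recomputed from the rounded counts, so the tables
    are internally consistent (TPM proportional to count / length) and carry
    realistic rounding error relative to the truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config)

    _write_gff3(truth.direction.index, truth.structure, outdir / "annotation.gff3")

    lengths = np.array(
        [
            _transcript_length(
                _gene_layout(i, truth.structure.iloc[i])["exons"][role]
            )
            for i in range(config.n_genes)
            for role in ("prox", "dist")
        ],
        dtype=float,
    )
    effective = np.maximum(lengths - 200.0, 1.0)

    rows = []
    for sample in truth.sample_conditions.index:
        counts = truth.target_counts[sample].to_numpy()
        rate = counts / lengths
        tpm_obs = rate / rate.sum() * 1e6
        table = pd.DataFrame(
            {
                "Name": truth.target_counts.index,
                "Length": lengths.astype(int),
                "EffectiveLength": effective,
                "TPM": tpm_obs,
                "NumReads": counts,
            }
        )
        path = outdir / f"{sample}.quant.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6f")
        rows.append(
            {
                "sample_id": sample,
                "path": path.name,
                "condition": truth.sample_conditions[sample],
                "replicate": sample.split("_rep")[1],
            }
        )

    pd.DataFrame(rows).to_csv(outdir / "samplesheet.tsv", sep="\t", index=False)

    truth_out = pd.concat(
        [truth.direction, truth.structure, truth.gene_tpm, truth.psi], axis=1
    )
    truth_out.columns = ["direction", "structure", "gene_tpm"] + [
        f"psi_{s}" for s in truth.psi.columns
    ]
    truth_out.to_csv(outdir / "truth.tsv", sep="\t", float_format="%.8f")
    return truth


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ---------------------------------------------------------------------------
# Caller evaluation
# ---------------------------------------------------------------------------


@dataclass
class Evaluation:
    """Confusion matrix and per-class accuracy of an APA caller vs truth."""

    confusion: pd.DataFrame  # rows true class, columns called class
    sensitivity: pd.Series
    precision: pd.Series

    @property
    def affected_sensitivity(self) -> float:
        """Recall over truly changed genes (positive + negative), requiring
        the called direction to match the true direction."""
        affected = self.confusion.loc[["positive", "negative"]]
        correct = (
            self.confusion.loc["positive", "positive"]
            + self.confusion.loc["negative", "negative"]
        )
        total = affected.to_numpy().sum()
        return correct / total if total else math.nan

    @property
    def false_discovery_proportion(self) -> float:
        """Fraction of affected calls (positive or negative) that are wrong —
        truly control, or truly changed in the opposite direction."""
        called = self.confusion[["positive", "negative"]]
        total = called.to_numpy().sum()
        correct = (
            self.confusion.loc["positive", "positive"]
            + self.confusion.loc["negative", "negative"]
        )
        return (total - correct) / total if total else math.nan


def evaluate_calls(
    results: pd.DataFrame,
    truth: pd.DataFrame | pd.Series,
    fdr: float = 0.05,
) -> Evaluation:
    """Score differential-APA calls against the simulation truth.

    A gene is called positive (negative) when its q-value is below ``fdr``
    and its reported delta-psi is positive (negative); all other genes —
    including genes the caller could not test — are called control.
    """
    true_class = truth["direction"] if isinstance(truth, pd.DataFrame) else truth
    missing = sorted(set(true_class.index) ^ set(results.index))
    if missing:
        raise ValueError(
            f"results and truth disagree on {len(missing)} gene id(s): "
            f"{missing[:10]}"
        )

    qval = results["qval"].reindex(true_class.index)
    dpsi = results["deltapsi"].reindex(true_class.index)
    called = pd.Series("control", index=true_class.index)
    hit = (qval < fdr) & dpsi.notna() & (dpsi != 0)
    called[hit & (dpsi > 0)] = "positive"
    called[hit & (dpsi < 0)] = "negative"

    confusion = (
        pd.crosstab(true_class, called)
        .reindex(index=DIRECTIONS, columns=DIRECTIONS, fill_value=0)
        .rename_axis(index="true", columns="called")
    )
    diag = pd.Series(np.diag(confusion), index=confusion.index, dtype=float)
    sensitivity = diag / confusion.sum(axis=1).replace(0, np.nan)
    precision = diag / confusion.sum(axis=0).replace(0, np.nan)
    return Evaluation(
        confusion=confusion, sensitivity=sensitivity, precision=precision
    )
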