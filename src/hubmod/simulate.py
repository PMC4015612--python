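"""Synthetic expression/network generator with planted correlation
structure.

Each planted module is a star: a hub gene and ``n_partners`` partner
genes.  Within condition ``c`` the hub's samples are drawn i.i.d.
standard normal and each partner is built as

    partner = rho[c] * hub + sqrt(1 - rho[c]**2) * noise,

scaled by ``noise_sd``, so the *population* hub-partner Pearson
correlation in condition ``c`` is exactly ``rho[c]`` (the scaling leaves
correlations untouched).  Background genes are independent noise and
carry no network edges.  A module is dysregulated by construction iff
its rho differs between some pair of conditions — dysregulation is
planted only through correlation, never through mean shifts, which is
exactly the signal the differential-correlation test targets (and what
differential-expression methods miss).

A Student-t (5 df) noise family is available to stress the Spearman
path with heavy tails.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (ConditionLabels, ExpressionMatrix, HubTestResult,
                         Network, ValidationError)
from .network import clean_network

logger = logging.getLogger(__name__)


@dataclass
class ModuleSpec:
    """One planted star module: per-condition target correlation."""

    hub_id: str
    n_partners: int
    rho: dict[str, float]
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_partners < 1:
            raise ValidationError("n_partners must be >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        for c, r in self.rho.items():
            if not -1.0 <= r <= 1.0:
                raise ValidationError(
                    f"rho[{c!r}] = {r} outside [-1, 1]")

    @property
    def dysregulated(self) -> bool:
        values = list(self.rho.values())
        return any(abs(v - values[0]) > 1e-12 for v in values[1:])


@dataclass
class SimulationDesign:
    modules: list[ModuleSpec]
    n_background_genes: int = 0
    samples_per_condition: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    family: str = "normal"

    def __post_init__(self) -> None:
        if len(self.samples_per_condition) < 2:
            raise ValidationError("need at least 2 conditions")
        for c, n in self.samples_per_condition.items():
            if n < 3:
                raise ValidationError(
                    f"condition {c!r} needs >= 3 samples, got {n}")
        if self.family not in ("normal", "t5"):
            raise ValidationError(f"unknown noise family {self.family!r}")
        ids = [m.hub_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate hub IDs in design")
        for m in self.modules:
            missing = set(self.samples_per_condition) - set(m.rho)
            if missing:
                raise ValidationError(
                    f"module {m.hub_id}: rho missing for conditions {missing}")


@dataclass
class SimulatedDataset:
    expression: ExpressionMatrix
    labels: ConditionLabels
    network: Network
    truth: pd.DataFrame


def _draw(rng: np.random.Generator, size, family: str) -> np.ndarray:
    if family == "t5":
        # unit-variance heavy-tailed noise
        return rng.standard_t(5, size=size) / np.sqrt(5.0 / 3.0)
    return rng.standard_normal(size=size)


def simulate_dataset(design: SimulationDesign) -> SimulatedDataset:
    """Generate (expression, labels, network, truth) from a design.

    Deterministic for a fixed design seed.  The truth table has one row
    per planted module with its per-condition rho and a ``dysregulated``
    flag.
    """
    rng = np.random.default_rng(design.seed)
    conditions = list(design.samples_per_condition)
    sample_ids: list[str] = []
    cond_of: dict[str, str] = {}
    for c in conditions:
        for i in range(design.samples_per_condition[c]):
            sid = f"{c}_s{i + 1:03d}"
            sample_ids.append(sid)
            cond_of[sid] = c
    cond_slices = {}
    start = 0
    for c in conditions:
        n = design.samples_per_condition[c]
        cond_slices[c] = slice(start, start + n)
        start += n
    n_samples = start

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    edges: list[tuple[str, str]] = []
    truth_rows = []
    for spec in design.modules:
        hub_row = np.empty(n_samples)
        partner_rows = np.empty((spec.n_partners, n_samples))
        for c in conditions:
            sl = cond_slices[c]
            n = design.samples_per_condition[c]
            hub = _draw(rng, n, design.family)
            noise = _draw(rng, (spec.n_partners, n), design.family)
            rho = spec.rho[c]
            hub_row[sl] = hub
            partner_rows[:, sl] = (rho * hub
                                   + np.sqrt(1.0 - rho ** 2) * noise)
        gene_ids.append(spec.hub_id)
        rows.append(hub_row)
        for j in range(spec.n_partners):
            pid = f"{spec.hub_id}_P{j + 1:02d}"
            gene_ids.append(pid)
            rows.append(spec.noise_sd * partner_rows[j])
            edges.append((spec.hub_id, pid))
        truth_row = {"hub": spec.hub_id, "n_partners": spec.n_partners,
                     "dysregulated": spec.dysregulated}
        for c in conditions:
            truth_row[f"rho_{c}"] = spec.rho[c]
        truth_rows.append(truth_row)

    for i in range(design.n_background_genes):
        gene_ids.append(f"BG{i + 1:04d}")
        rows.append(_draw(rng, n_samples, design.family))
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("gene IDs across modules/background collide")

    expr = ExpressionMatrix(pd.DataFrame(
        np.vstack(rows), index=gene_ids, columns=sample_ids))
    labels = ConditionLabels(dict(cond_of))
    network = clean_network(edges, directed=False)
    truth = pd.DataFrame(truth_rows)
    logger.info("simulated %d genes x %d samples, %d modules "
                "(%d dysregulated), %d background genes",
                len(gene_ids), n_samples, len(design.modules),
                int(truth["dysregulated"].sum()) if len(truth) else 0,
                design.n_background_genes)
    return SimulatedDataset(expression=expr, labels=labels,
                            network=network, truth=truth)


def two_condition_design(n_null: int, n_dysregulated: int,
                         rho_null: float = 0.5,
                         rho_a: float = 0.8, rho_b: float = 0.0,
                         n_partners: int = 10,
                         samples_per_condition: int = 30,
                         conditions: tuple[str, str] = ("A", "B"),
                         n_background_genes: int = 0,
                         seed: int = 0) -> SimulationDesign:
    """Convenience two-condition design: ``n_null`` modules with equal
    correlation in both conditions plus ``n_dysregulated`` modules with
    rho_a vs rho_b."""
    ca, cb = conditions
    modules = [ModuleSpec(hub_id=f"DYS{i + 1:03d}", n_partners=n_partners,
                          rho={ca: rho_a, cb: rho_b})
               for i in range(n_dysregulated)]
    modules += [ModuleSpec(hub_id=f"NULL{i + 1:03d}", n_partners=n_partners,
                           rho={ca: rho_null, cb: rho_null})
                for i in range(n_null)]
    return SimulationDesign(
        modules=modules, n_background_genes=n_background_genes,
        samples_per_condition={ca: samples_per_condition,
                               cb: samples_per_condition},
        seed=seed)


def evaluate_recovery(results: list[HubTestResult], truth: pd.DataFrame,
                      alpha: float = 0.05) -> tuple[float, float]:
    """(type-I error rate, power) of a result set against the truth table.

    Type-I rate: fraction of truly-null modules called at ``p <= alpha``;
    power: fraction of truly-dysregulated modules called.  Every truth
    hub must appear in the results.
    """
    by_hub = {r.hub: r for r in results}
    missing = [h for h in truth["hub"] if h not in by_hub]
    if missing:
        raise ValidationError(
            f"truth-table hubs absent from results: {missing[:5]}")
    null_calls = []
    dys_calls = []
    for _, row in truth.iterrows():
        called = by_hub[row["hub"]].p_value <= alpha
        (dys_calls if row["dysregulated"] else null_calls).append(called)
    type_i = float(np.mean(null_calls)) if null_calls else 0.0
    power = float(np.mean(dys_calls)) if dys_calls else 0.0
    return type_i, power
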