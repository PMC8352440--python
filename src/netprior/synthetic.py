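"""Planted-module benchmark generator.

Emits the three pipeline inputs — weighted network, disease-gene
associations, disease-disease similarities — with known ground truth, so
that recovery can be measured exactly without external databases.

The network is a planted-partition graph: genes are split into modules,
edges appear with probability ``p_within`` inside a module and
``p_between`` across modules, and every edge carries a uniform weight.
Each disease draws most of its genes from one module (a ``leak_fraction``
comes from elsewhere), so diseases sharing a module share genes — the
"similar diseases have similar genes" premise in miniature. Disease
similarity is the Jaccard overlap of the emitted gene sets. A fraction of
the target disease's genes is withheld from the association table (but
kept in the network) as the "novel" genes a prioritizer should recover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as nio

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkConfig", "BenchmarkTruth", "generate"]

#: Minimum fraction of genes that must sit in the largest connected
#: component for a generated network to be accepted.
GIANT_COMPONENT_MIN = 0.9
MAX_REGENERATION_ATTEMPTS = 10


@dataclass
class BenchmarkConfig:
    """Parameters of the planted benchmark (defaults are the study conditions)."""

    n_modules: int = 4
    genes_per_module: int = 50
    p_within: float = 0.3
    p_between: float = 0.02
    weight_low: float = 0.1
    weight_high: float = 1.0
    n_diseases: int = 8
    target_module: int = 0
    genes_per_disease: int = 25
    leak_fraction: float = 0.1
    holdout_fraction: float = 0.2
    seed: int = 7

    def validate(self) -> None:
        if min(self.n_modules, self.genes_per_module, self.n_diseases,
               self.genes_per_disease) <= 0:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.p_between < self.p_within <= 1.0):
            raise ValueError("require 0 <= p_between < p_within <= 1")
        if not (0.0 < self.weight_low <= self.weight_high):
            raise ValueError("weights must satisfy 0 < low <= high")
        if not (0.0 <= self.leak_fraction < 1.0):
            raise ValueError("leak_fraction must be in [0, 1)")
        if not (0.0 <= self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in [0, 1)")
        if not (0 <= self.target_module < self.n_modules):
            raise ValueError("target_module out of range")
        n_in = self.genes_per_disease - round(self.genes_per_disease * self.leak_fraction)
        if n_in > self.genes_per_module:
            raise ValueError(
                f"impossible config: {n_in} within-module disease genes "
                f"requested but modules hold only {self.genes_per_module} genes"
            )
        if self.genes_per_disease > self.n_modules * self.genes_per_module:
            raise ValueError("more disease genes than genes in the network")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class BenchmarkTruth:
    """Ground truth of one generated benchmark instance."""

    config: BenchmarkConfig
    target_disease: str
    module_of: dict[str, int]
    disease_module: dict[str, int]
    disease_genes: dict[str, set[str]] = field(repr=False, default_factory=dict)
    heldout_targets: set[str] = field(default_factory=set)
    files: dict[str, Path] = field(default_factory=dict)
    network: nio.GeneNetwork | None = field(default=None, repr=False)
    associations: nio.DiseaseGeneAssociations | None = field(default=None, repr=False)
    similarities: nio.DiseaseSimilarityTable | None = field(default=None, repr=False)


def _planted_partition(
    module_of: dict[str, int], cfg: BenchmarkConfig, seed: int
) -> nio.GeneNetwork:
    genes = sorted(module_of)
    rng = np.random.default_rng(seed)
    net = nio.GeneNetwork()
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            same = module_of[genes[i]] == module_of[genes[j]]
            p = cfg.p_within if same else cfg.p_between
            if rng.random() < p:
                w = rng.uniform(cfg.weight_low, cfg.weight_high)
                net.add_edge(genes[i], genes[j], float(w))
    return net


def _giant_component_fraction(net: nio.GeneNetwork, n_genes: int) -> float:
    import networkx as nx
    if net.graph.number_of_nodes() == 0:
        return 0.0
    largest = max(nx.connected_components(net.graph), key=len)
    return len(largest) / n_genes


def generate(config: BenchmarkConfig, out_dir: str | Path) -> BenchmarkTruth:
    """Generate one benchmark instance and write its TSVs to ``out_dir``.

    The network must place at least 90% of genes in one connected
    component; otherwise generation is retried with an incremented seed
    (logged, at most 10 attempts). Identical config and seed yield
    byte-identical files.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes = [
        f"G{m * config.genes_per_module + i:04d}"
        for m in range(config.n_modules)
        for i in range(config.genes_per_module)
    ]
    module_of = {g: idx // config.genes_per_module for idx, g in enumerate(genes)}

    # p_between == 0 declares intentionally disconnected modules, so the
    # giant-component requirement is waived for that degenerate case.
    net: nio.GeneNetwork | None = None
    for attempt in range(MAX_REGENERATION_ATTEMPTS):
        candidate = _planted_partition(module_of, config, config.seed + attempt)
        frac = _giant_component_fraction(candidate, len(genes))
        if config.p_between == 0.0 or frac >= GIANT_COMPONENT_MIN:
            net = candidate
            break
        logger.warning(
            "attempt %d: giant component holds %.0f%% of genes (< %.0f%%); "
            "regenerating with incremented seed",
            attempt, 100 * frac, 100 * GIANT_COMPONENT_MIN,
        )
    if net is None:
        raise RuntimeError(
            f"no network with a >= {GIANT_COMPONENT_MIN:.0%} giant component "
            f"in {MAX_REGENERATION_ATTEMPTS} attempts; raise p_within/p_between"
        )

    # disease gene sets: disease i sits in module (target_module + i) % M,
    # so disease 0 is the target and later diseases cycle over modules.
    rng = np.random.default_rng(config.seed + 1_000_003)
    by_module: dict[int, list[str]] = {}
    for g, m in module_of.items():
        by_module.setdefault(m, []).append(g)
    for m in by_module:
        by_module[m].sort()

    diseases = [f"D{i:02d}" for i in range(config.n_diseases)]
    disease_module = {
        d: (config.target_module + i) % config.n_modules
        for i, d in enumerate(diseases)
    }
    n_leak = round(config.genes_per_disease * config.leak_fraction)
    n_in = config.genes_per_disease - n_leak
    disease_genes: dict[str, set[str]] = {}
    for d in diseases:
        m = disease_module[d]
        inside = by_module[m]
        outside = sorted(set(genes) - set(inside))
        picked = {str(g) for g in rng.choice(inside, size=n_in, replace=False)}
        if n_leak:
            picked |= {str(g) for g in rng.choice(outside, size=n_leak, replace=False)}
        disease_genes[d] = picked

    target = diseases[0]
    target_genes = sorted(disease_genes[target])
    n_hold = round(config.holdout_fraction * len(target_genes))
    heldout = (
        {str(g) for g in rng.choice(target_genes, size=n_hold, replace=False)}
        if n_hold else set()
    )

    emitted = {
        d: (gs - heldout if d == target else set(gs))
        for d, gs in disease_genes.items()
    }
    assoc = nio.DiseaseGeneAssociations(
        entries=sorted((d, g) for d, gs in emitted.items() for g in gs)
    )

    sim = nio.DiseaseSimilarityTable()
    for i, a in enumerate(diseases):
        for b in diseases[i + 1:]:
            inter = len(emitted[a] & emitted[b])
            if inter:
                union = len(emitted[a] | emitted[b])
                sim.add(a, b, inter / union)

    files = {
        "network": out_dir / "network.tsv",
        "associations": out_dir / "associations.tsv",
        "similarities": out_dir / "similarities.tsv",
        "truth": out_dir / "truth.tsv",
    }
    nio.write_network(net, files["network"])
    nio.write_associations(assoc, files["associations"])
    nio.write_similarities(sim, files["similarities"])
    _write_truth(files["truth"], target, module_of, disease_module, heldout)

    return BenchmarkTruth(
        config=config,
        target_disease=target,
        module_of=module_of,
        disease_module=disease_module,
        disease_genes=disease_genes,
        heldout_targets=heldout,
        files=files,
        network=net,
        associations=assoc,
        similarities=sim,
    )


def _write_truth(
    path: Path,
    target: str,
    module_of: dict[str, int],
    disease_module: dict[str, int],
    heldout: set[str],
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("record\tid\tvalue\n")
        fh.write(f"target\t{target}\t1\n")
        for d in sorted(disease_module):
            fh.write(f"disease_module\t{d}\t{disease_module[d]}\n")
        for g in sorted(module_of):
            fh.write(f"gene_module\t{g}\t{module_of[g]}\n")
        for g in sorted(heldout):
            fh.write(f"heldout\t{g}\t1\n")
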