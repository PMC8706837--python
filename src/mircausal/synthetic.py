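"""Synthetic benchmark generator with planted family/subtree structure.

The generator emulates the statistical structure the predictor exploits in
real data, so the whole pipeline is testable without any database download:

* miRNAs come in sequence families: each family has random ancestral
  precursor (80 nt), mature (22 nt) and seed (7 nt) sequences over
  {A,C,G,U}, and members are per-base mutated copies, so within-family
  edit similarity exceeds between-family similarity in expectation;
* expression profiles are family means per cell type plus Gaussian noise;
* pathway enrichment p-values are strongly significant on a family-specific
  pathway set and non-significant elsewhere;
* diseases form a random rooted tree serialized as MeSH-style tree numbers;
* causal links are planted in (family x disease-subtree) blocks: block
  cells are causal with probability ``coupling`` and otherwise non-causal
  with probability ``noncausal_rate`` (same biology, weaker evidence, which
  makes causal/non-causal discrimination genuinely harder than
  causal/none); background cells are randomly labeled at ``noise_rate``.

All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .types import ConfigurationError

BASES = np.array(list("ACGU"))

PRECURSOR_LEN = 80
MATURE_LEN = 22
SEED_LEN = 7


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic benchmark."""

    n_mirnas: int = 60
    n_diseases: int = 40
    n_families: int = 6
    n_cell_types: int = 20
    n_pathways: int = 60
    mutation_rate: float = 0.10
    coupling: float = 0.8
    noncausal_rate: float = 0.15
    noise_rate: float = 0.02
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "coupling", "noncausal_rate", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_mirnas", "n_diseases", "n_families", "n_cell_types", "n_pathways"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_families > self.n_mirnas:
            raise ConfigurationError("cannot have more families than miRNAs")
        if self.coupling + self.noncausal_rate > 1.0 or 2 * self.noise_rate > 1.0:
            raise ConfigurationError("label probabilities exceed 1")


@dataclass
class SyntheticDataset:
    """Complete input bundle plus the planted ground truth."""

    precursor_seqs: dict[str, str]
    mature_seqs: dict[str, str]
    seed_seqs: dict[str, str]
    expression: pd.DataFrame
    pathways: pd.DataFrame
    mesh_mapping: dict[str, list[str]]
    association_table: pd.DataFrame
    family_of: dict[str, int]
    blocks: dict[int, list[str]] = field(default_factory=dict)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.precursor_seqs)

    @property
    def disease_ids(self) -> list[str]:
        return list(self.mesh_mapping)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = np.array(list(seq))
    hits = rng.random(len(chars)) < rate
    for i in np.nonzero(hits)[0]:
        choices = BASES[BASES != chars[i]]
        chars[i] = rng.choice(choices)
    return "".join(chars)


def _random_disease_tree(rng: np.random.Generator, n: int) -> tuple[list[str], dict[str, list[str]], list[list[int]]]:
    """Random recursive tree; returns names, tree-number mapping, children lists."""
    names = [f"synthetic disease {i:02d}" for i in range(n)]
    parent = [-1] * n
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n):
        p = int(rng.integers(0, i))
        parent[i] = p
        children[p].append(i)
    codes = [""] * n
    codes[0] = "C01"
    # assign codes in BFS order so a parent's code exists before its children's
    order = [0]
    for node in order:
        for rank, child in enumerate(children[node], start=1):
            codes[child] = f"{codes[node]}.{rank:03d}"
            order.append(child)
    mapping = {names[i]: [codes[i]] for i in range(n)}
    return names, mapping, children


def _subtree(children: list[list[int]], root: int) -> list[int]:
    out = [root]
    for node in out:
        out.extend(children[node])
    return out


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic input bundle, deterministic in config.seed."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    mirna_ids = [f"hsa-mir-{i + 1:04d}" for i in range(config.n_mirnas)]
    family_of = {m: i % config.n_families for i, m in enumerate(mirna_ids)}

    ancestors = {
        f: {
            "precursor": _random_seq(rng, PRECURSOR_LEN),
            "mature": _random_seq(rng, MATURE_LEN),
            "seed": _random_seq(rng, SEED_LEN),
        }
        for f in range(config.n_families)
    }
    precursor_seqs, mature_seqs, seed_seqs = {}, {}, {}
    for m in mirna_ids:
        anc = ancestors[family_of[m]]
        precursor_seqs[m] = _mutate(rng, anc["precursor"], config.mutation_rate)
        mature_seqs[m] = _mutate(rng, anc["mature"], config.mutation_rate)
        seed_seqs[m] = _mutate(rng, anc["seed"], config.mutation_rate)

    cell_types = [f"cell_type_{c:02d}" for c in range(config.n_cell_types)]
    family_means = rng.uniform(0.0, 10.0, size=(config.n_families, config.n_cell_types))
    expr = np.vstack(
        [family_means[family_of[m]] + rng.normal(0.0, 1.0, config.n_cell_types) for m in mirna_ids]
    )
    expression = pd.DataFrame(np.round(expr, 4), index=mirna_ids, columns=cell_types)

    pathway_names = [f"pathway_{p:03d}" for p in range(config.n_pathways)]
    n_sig = max(1, config.n_pathways // 5)
    family_pathways = {
        f: set(rng.choice(config.n_pathways, size=n_sig, replace=False).tolist())
        for f in range(config.n_families)
    }
    pvals = np.empty((config.n_mirnas, config.n_pathways))
    for i, m in enumerate(mirna_ids):
        sig = family_pathways[family_of[m]]
        for j in range(config.n_pathways):
            if j in sig:
                pvals[i, j] = rng.uniform(1e-6, 0.04)
            else:
                pvals[i, j] = rng.uniform(0.06, 1.0)
    pathways = pd.DataFrame(pvals, index=mirna_ids, columns=pathway_names)

    disease_names, mesh_mapping, children = _random_disease_tree(rng, config.n_diseases)

    # one disease-subtree block per family; prefer mid-sized subtrees
    sizes = [len(_subtree(children, i)) for i in range(config.n_diseases)]
    hi = max(3, config.n_diseases // 3)
    candidates = [i for i, s in enumerate(sizes) if 3 <= s <= hi]
    if not candidates:
        candidates = list(range(config.n_diseases))
    blocks: dict[int, list[str]] = {}
    block_cells: dict[tuple[str, str], int] = {}
    for f in range(config.n_families):
        root = int(rng.choice(candidates))
        members = [disease_names[i] for i in _subtree(children, root)]
        blocks[f] = members
        for m in mirna_ids:
            if family_of[m] == f:
                for d in members:
                    block_cells[(m, d)] = f

    rows: list[tuple[str, str, str]] = []
    for m in mirna_ids:
        for d in disease_names:
            u = rng.random()
            if (m, d) in block_cells:
                if u < config.coupling:
                    rows.append((m, d, "causal"))
                elif u < config.coupling + config.noncausal_rate:
                    rows.append((m, d, "non-causal"))
            else:
                if u < config.noise_rate:
                    rows.append((m, d, "causal"))
                elif u < 2 * config.noise_rate:
                    rows.append((m, d, "non-causal"))

    table = pd.DataFrame(rows, columns=["mirna", "disease", "label"])
    table = _pad_universe(table, mirna_ids, disease_names)
    return SyntheticDataset(
        precursor_seqs,
        mature_seqs,
        seed_seqs,
        expression,
        pathways,
        mesh_mapping,
        table,
        family_of,
        blocks,
    )


def _pad_universe(table: pd.DataFrame, mirna_ids: list[str], disease_ids: list[str]) -> pd.DataFrame:
    """Append explicit 'none' rows so every entity appears in the table.

    The association-matrix universe is defined by the table; entities whose
    every cell is unassociated would otherwise drop out of the benchmark.
    """
    pad: list[tuple[str, str, str]] = []
    seen_m = set(table["mirna"])
    seen_d = set(table["disease"])
    for m in mirna_ids:
        if m not in seen_m:
            pad.append((m, disease_ids[0], "none"))
    for d in disease_ids:
        if d not in seen_d:
            pad.append((mirna_ids[0], d, "none"))
    if pad:
        table = pd.concat(
            [table, pd.DataFrame(pad, columns=["mirna", "disease", "label"])],
            ignore_index=True,
        )
    return table.drop_duplicates(subset=["mirna", "disease"], keep="first").reset_index(drop=True)


def randomize_labels(dataset: SyntheticDataset, seed: int) -> pd.DataFrame:
    """Null-control table: same label counts, placed uniformly at random.

    Destroys the planted coupling between miRNA families and disease
    subtrees while preserving the marginal label frequencies, so a sound
    pipeline should score causal vs non-causal near chance on it.
    """
    rng = np.random.default_rng(seed)
    counts = dataset.association_table["label"].value_counts()
    n_causal = int(counts.get("causal", 0))
    n_noncausal = int(counts.get("non-causal", 0))
    mirnas = dataset.mirna_ids
    diseases = dataset.disease_ids
    n_cells = len(mirnas) * len(diseases)
    chosen = rng.choice(n_cells, size=n_causal + n_noncausal, replace=False)
    rows = []
    for pos, flat in enumerate(chosen):
        label = "causal" if pos < n_causal else "non-causal"
        rows.append((mirnas[flat // len(diseases)], diseases[flat % len(diseases)], label))
    table = pd.DataFrame(rows, columns=["mirna", "disease", "label"])
    return _pad_universe(table, mirnas, diseases)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in exactly the formats the io module reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _fasta(name: str, seqs: Mapping[str, str]) -> None:
        p = outdir / f"{name}.fa"
        with open(p, "w") as fh:
            for sid, seq in seqs.items():
                fh.write(f">{sid}\n{seq}\n")
        paths[name] = p

    _fasta("precursor", dataset.precursor_seqs)
    _fasta("mature", dataset.mature_seqs)
    _fasta("seed", dataset.seed_seqs)

    paths["expression"] = outdir / "expression.tsv"
    dataset.expression.to_csv(paths["expression"], sep="\t")
    paths["pathways"] = outdir / "pathways.tsv"
    dataset.pathways.to_csv(paths["pathways"], sep="\t")

    paths["mesh"] = outdir / "mesh_mapping.tsv"
    with open(paths["mesh"], "w") as fh:
        fh.write("disease\ttree_numbers\n")
        for name, codes in dataset.mesh_mapping.items():
            fh.write(f"{name}\t{';'.join(codes)}\n")

    paths["associations"] = outdir / "associations.tsv"
    dataset.association_table.rename(columns={"label": "causality"}).to_csv(
        paths["associations"], sep="\t", index=False
    )
    return paths
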