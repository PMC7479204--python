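"""Planted-block synthetic herb-ingredient datasets.

Emulates the shape of a curated herb-ingredient resource: a bipartite graph
with planted community (block) structure plus four block-correlated
annotations — meridian and property label sets for herbs, SMILES-like
strings and protein-target sets for ingredients.  Each block owns an
ingredient pool and a signature for every annotation; herbs draw their
ingredients mostly from their own block's pool (``cross_block_rate``
controls leakage) and entities inherit their block's signature subject to
``annotation_noise`` / ``string_mutation_rate`` corruption.  Ground-truth
block memberships are returned for recovery and calibration tests.

All randomness flows through one ``numpy`` Generator seeded once; draws
occur in a fixed documented order (block signatures, then incidence, then
herb annotations, then ingredient annotations), so the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bigraph import IncidenceTable
from .errors import ConfigError
from .validation import AnnotationTable

#: symbols common in SMILES; chemical validity is a non-goal
ALPHABET = list("CcNO=()12SF[")

ANNOTATION_KINDS = {
    "meridian": "label_set",
    "property": "label_set",
    "smiles": "string",
    "target": "id_set",
}


@dataclass
class SyntheticConfig:
    """Parameters of the planted-block generator.

    Defaults describe a small three-block universe: 20 herbs and 30
    ingredients per block, 6 ingredient draws per herb with 5% cross-block
    leakage, and 10% annotation corruption — enough structure for community
    recovery while keeping runs fast.
    """

    n_blocks: int = 3
    herbs_per_block: int = 20
    ingredients_per_block: int = 30
    ingredients_per_herb: int = 6
    cross_block_rate: float = 0.05
    annotation_noise: float = 0.1
    n_meridian_labels: int = 12
    n_property_labels: int = 8
    n_target_labels: int = 60
    labels_per_entity: int = 3
    string_length: int = 24
    string_mutation_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_blocks": self.n_blocks,
            "herbs_per_block": self.herbs_per_block,
            "ingredients_per_block": self.ingredients_per_block,
            "ingredients_per_herb": self.ingredients_per_herb,
            "n_meridian_labels": self.n_meridian_labels,
            "n_property_labels": self.n_property_labels,
            "n_target_labels": self.n_target_labels,
            "labels_per_entity": self.labels_per_entity,
            "string_length": self.string_length,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        probs = {
            "cross_block_rate": self.cross_block_rate,
            "annotation_noise": self.annotation_noise,
            "string_mutation_rate": self.string_mutation_rate,
        }
        for name, v in probs.items():
            if not math.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0,1], got {v!r}")
        for name, universe in (
            ("n_meridian_labels", self.n_meridian_labels),
            ("n_property_labels", self.n_property_labels),
            ("n_target_labels", self.n_target_labels),
        ):
            if self.labels_per_entity > universe:
                raise ConfigError(
                    f"labels_per_entity exceeds {name} ({self.labels_per_entity} > {universe})"
                )


@dataclass
class GroundTruth:
    """Planted block membership of every generated entity."""

    herb_block: dict[str, int]
    ingredient_block: dict[str, int]

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(f"entity_id{delimiter}block\n")
            for entity in sorted(self.herb_block):
                fh.write(f"{entity}{delimiter}{self.herb_block[entity]}\n")
            for entity in sorted(self.ingredient_block):
                fh.write(f"{entity}{delimiter}{self.ingredient_block[entity]}\n")


def _noisy_labels(
    signature: list, universe: list, noise: float, rng: np.random.Generator
) -> frozenset:
    out = []
    for lab in signature:
        if rng.random() < noise:
            out.append(universe[rng.integers(len(universe))])
        else:
            out.append(lab)
    return frozenset(out)


def _mutated_string(signature: str, rate: float, rng: np.random.Generator) -> str:
    chars = []
    for ch in signature:
        if rng.random() < rate:
            chars.append(ALPHABET[rng.integers(len(ALPHABET))])
        else:
            chars.append(ch)
    return "".join(chars)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[IncidenceTable, dict[str, AnnotationTable], GroundTruth]:
    """Generate a planted-block dataset.

    Returns the incidence table, a dict of four annotation tables keyed
    ``meridian``/``property``/``smiles``/``target``, and the ground truth.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    B = config.n_blocks
    width = max(4, len(str(B * max(config.herbs_per_block, config.ingredients_per_block))))

    herbs = {
        b: [f"H{b * config.herbs_per_block + i + 1:0{width}d}" for i in range(config.herbs_per_block)]
        for b in range(B)
    }
    ingredients = {
        b: [
            f"I{b * config.ingredients_per_block + i + 1:0{width}d}"
            for i in range(config.ingredients_per_block)
        ]
        for b in range(B)
    }

    meridians = [f"M{i:02d}" for i in range(config.n_meridian_labels)]
    properties = [f"P{i:02d}" for i in range(config.n_property_labels)]
    targets = [f"T{i:03d}" for i in range(config.n_target_labels)]

    # 1) block signatures, in block order
    sig = {b: {} for b in range(B)}
    for b in range(B):
        sig[b]["meridian"] = [
            meridians[i]
            for i in rng.choice(len(meridians), config.labels_per_entity, replace=False)
        ]
        sig[b]["property"] = [
            properties[i]
            for i in rng.choice(len(properties), config.labels_per_entity, replace=False)
        ]
        sig[b]["target"] = [
            targets[i]
            for i in rng.choice(len(targets), config.labels_per_entity, replace=False)
        ]
        sig[b]["smiles"] = "".join(
            ALPHABET[i] for i in rng.integers(len(ALPHABET), size=config.string_length)
        )

    # 2) incidence draws, herb by herb in block order
    rows: list[tuple[str, str]] = []
    for b in range(B):
        for herb in herbs[b]:
            for _ in range(config.ingredients_per_herb):
                if B > 1 and rng.random() < config.cross_block_rate:
                    foreign = [x for x in range(B) if x != b]
                    pool = ingredients[foreign[rng.integers(len(foreign))]]
                else:
                    pool = ingredients[b]
                rows.append((herb, pool[rng.integers(len(pool))]))
    incidence = IncidenceTable(rows)

    # 3) herb annotations, 4) ingredient annotations
    meridian_payload, property_payload = {}, {}
    for b in range(B):
        for herb in herbs[b]:
            meridian_payload[herb] = _noisy_labels(
                sig[b]["meridian"], meridians, config.annotation_noise, rng
            )
            property_payload[herb] = _noisy_labels(
                sig[b]["property"], properties, config.annotation_noise, rng
            )
    smiles_payload, target_payload = {}, {}
    for b in range(B):
        for ing in ingredients[b]:
            smiles_payload[ing] = _mutated_string(
                sig[b]["smiles"], config.string_mutation_rate, rng
            )
            target_payload[ing] = _noisy_labels(
                sig[b]["target"], targets, config.annotation_noise, rng
            )

    annotations = {
        "meridian": AnnotationTable("label_set", meridian_payload),
        "property": AnnotationTable("label_set", property_payload),
        "smiles": AnnotationTable("string", smiles_payload),
        "target": AnnotationTable("id_set", target_payload),
    }
    truth = GroundTruth(
        herb_block={h: b for b in range(B) for h in herbs[b]},
        ingredient_block={i: b for b in range(B) for i in ingredients[b]},
    )
    return incidence, annotations, truth


def write_dataset(
    incidence: IncidenceTable,
    annotations: dict[str, AnnotationTable],
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the generated dataset as TSVs; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"incidence": outdir / "incidence.tsv"}
    incidence.write(paths["incidence"])
    for name, table in annotations.items():
        paths[name] = outdir / f"{name}.tsv"
        table.write(paths[name])
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    truth.write(paths["ground_truth"])
    return paths
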