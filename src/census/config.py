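"""Run configuration and deterministic seed derivation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(master_seed: int, tag: str) -> int:
    """Stable child seed derived from a master seed and a purpose tag.

    Uses SHA-256 so the mapping is identical across platforms and Python
    processes (unlike ``hash``). Result is always < 2**31.
    """
    digest = hashlib.sha256(f"{master_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All tunable parameters for training and annotation.

    Defaults follow the method's stated conventions: 90% sparsification of
    the supplementary training copy, marker significance at adjusted p < 0.05
    with Bonferroni adjustment, and one 2D embedding per query clustered at
    roughly 10x the model's leaf count.
    """

    seed: int = 0
    # marker selection
    marker_alpha: float = 0.05
    marker_adjust: str = "bonferroni"  # or "fdr_bh"
    # training-data modification
    sparsify_fraction: float = 0.90
    # booster hyperparameters (conservative defaults; no tuning framework)
    booster_params: dict = field(
        default_factory=lambda: {
            "n_estimators": 60,
            "max_depth": 3,
            "learning_rate": 0.3,
            "tree_method": "hist",
            "n_jobs": 1,
        }
    )
    # embedding
    n_neighbors: int = 15
    min_dist: float = 0.3
    n_pcs: int = 10
    n_top_genes: int | None = None  # None: keep all genes (no HVG subsetting)
    scale: bool = False  # unit-variance scaling before PCA
    # fine clustering: target ~cluster_factor x number of leaf types
    cluster_factor: int = 10
    min_clusters: int = 10
    # label stabilization
    grid_size: int = 100
    contour_mass: float = 0.95  # fraction of a label's cells its contour encloses
    max_iter: int = 10
    stabilize: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def child_seed(self, tag: str) -> int:
        return derive_seed(self.seed, tag)
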