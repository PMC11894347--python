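"""Parameter bundle for the full path-ranking model and its checkpoint I/O.

Checkpoints are a directory holding a JSON parameter file (exact float64
round-trip via Python's shortest-repr floats) plus a shape manifest and a
config snapshot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import Tensor
from .ranker import ScorerKind, ScorerParams
from .sgin import SGINParams


@dataclass
class ModelParams:
    """All learnable parameters: SGIN (+ projection), path FFN, scorer."""

    dim: int
    onehot_size: int
    kind: ScorerKind
    sgin: SGINParams
    scorer: ScorerParams
    include_in_neighbors: bool = False

    @classmethod
    def init(cls, dim: int, onehot_size: int, kind: ScorerKind = "triattn",
             n_gin_layers: int = 2, heads: int = 4, hidden: int | None = None,
             include_in_neighbors: bool = False, seed: int = 0) -> "ModelParams":
        rng = np.random.default_rng(seed)
        return cls(
            dim=dim, onehot_size=onehot_size, kind=kind,
            sgin=SGINParams.init(dim, n_gin_layers, rng),
            scorer=ScorerParams.init(dim, onehot_size, kind, rng,
                                     heads=heads, hidden=hidden),
            include_in_neighbors=include_in_neighbors,
        )

    def parameters(self) -> list[Tensor]:
        return self.sgin.parameters() + self.scorer.parameters()

    # -- checkpointing -------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        params = self.parameters()
        payload = [p.data.tolist() for p in params]
        manifest = {
            "dim": self.dim,
            "onehot_size": self.onehot_size,
            "kind": self.kind,
            "heads": self.scorer.heads,
            "hidden": self.scorer.phi.W.shape[0],
            "n_gin_layers": len(self.sgin.layers),
            "include_in_neighbors": self.include_in_neighbors,
            "shapes": [list(p.shape) for p in params],
        }
        (out / "params.json").write_text(json.dumps(payload))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def load(cls, in_dir: str | Path) -> "ModelParams":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        model = cls.init(
            dim=manifest["dim"], onehot_size=manifest["onehot_size"],
            kind=manifest["kind"], n_gin_layers=manifest["n_gin_layers"],
            heads=manifest["heads"], hidden=manifest["hidden"],
            include_in_neighbors=manifest["include_in_neighbors"],
        )
        payload = json.loads((src / "params.json").read_text())
        params = model.parameters()
        if len(payload) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, values, shape in zip(params, payload, manifest["shapes"]):
            arr = np.asarray(values, dtype=np.float64).reshape(shape)
            if list(arr.shape) != list(p.shape):
                raise ValueError(
                    f"checkpoint shape {arr.shape} != expected {p.shape}"
                )
            p.data = arr
        return model
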