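"""Per-branch length/rate estimates for one dataset under one estimator."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .trees import UnrootedBranch


@dataclass
class BranchRateEstimates:
    """Estimated branch lengths on the unrooted topology and derived rates.

    Rates are ``length / time_span`` (substitutions/site/Myr). Branches whose
    estimated length falls below ``zero_threshold`` are flagged: a zero-length
    branch would imply an infinite fold variation, so flagged branches are
    excluded from ratio statistics downstream.
    """

    branches: list[UnrootedBranch]
    lengths: np.ndarray
    time_spans: np.ndarray
    estimator: str  # "ml" | "bayes"
    log_likelihood: Optional[float] = None
    kappa: Optional[float] = None
    zero_threshold: float = 1e-6
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.time_spans = np.asarray(self.time_spans, dtype=float)
        if len(self.branches) != len(self.lengths) or len(self.lengths) != len(self.time_spans):
            raise ValueError("branches, lengths and time_spans must align")

    @property
    def n_branches(self) -> int:
        return len(self.lengths)

    @property
    def rates(self) -> np.ndarray:
        return self.lengths / self.time_spans

    @property
    def zero_flags(self) -> np.ndarray:
        return self.lengths < self.zero_threshold

    def group_rates(self, grouping: str) -> dict[str, np.ndarray]:
        """Rates split by branch ``depth`` or ``clade`` tags.

        The central branch carries no depth (excluded from the depth
        contrast) and no single clade: its rate contributes to *both* clade
        averages, since it spans the two root subtrees.
        """
        rates = self.rates
        groups: dict[str, list[float]] = {}
        for b, r in zip(self.branches, rates):
            if grouping == "depth":
                if b.depth is not None:
                    groups.setdefault(str(b.depth), []).append(r)
            elif grouping == "clade":
                tags = [b.clade] if b.clade is not None else (["A", "B"] if b.is_central else [])
                for tag in tags:
                    groups.setdefault(tag, []).append(r)
            else:
                raise ValueError("grouping must be 'depth' or 'clade'")
        return {k: np.asarray(v) for k, v in groups.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "branch": [b.index for b in self.branches],
                "child_nodes": ["+".join(map(str, b.child)) for b in self.branches],
                "is_central": [b.is_central for b in self.branches],
                "depth": [b.depth for b in self.branches],
                "clade": [b.clade for b in self.branches],
                "length": self.lengths,
                "time_span": self.time_spans,
                "rate": self.rates,
                "zero_flag": self.zero_flags,
            }
        )
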