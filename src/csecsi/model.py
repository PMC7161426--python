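"""Model/Results interface over the coupled CP framework.

``CoupledCP`` is constructed from the two data tensors; ``fit`` runs the
semi-algebraic decomposition at an assumed rank and returns a
``CoupledCPResults`` carrying the factor estimates, the per-tensor residuals,
the reliability of the coupled solution, and the full candidate table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .framework import (
    CoupledResult,
    DecompositionOptions,
    csecsi,
    rank_sweep,
    secsi,
)
from .tensor import Tensor3, cp_reconstruct, ho_norm, _data

__all__ = ["CoupledCP", "CoupledCPResults"]


class CoupledCP:
    """Coupled CP model of two three-way tensors sharing their first mode."""

    def __init__(self, t1, t2, mode_names=None):
        self.t1 = t1 if isinstance(t1, Tensor3) else Tensor3(np.asarray(t1))
        self.t2 = t2 if isinstance(t2, Tensor3) else Tensor3(np.asarray(t2))
        if self.t1.dims[0] != self.t2.dims[0]:
            raise ValueError("tensors must share their first-mode dimension")
        if mode_names is not None:
            self.t1.mode_names = tuple(mode_names)
            self.t2.mode_names = tuple(mode_names)

    def fit(self, rank: int, options: DecompositionOptions | None = None) -> "CoupledCPResults":
        res = csecsi(self.t1, self.t2, rank, options)
        return CoupledCPResults(self, res)

    def rank_sweep(self, ranks, options: DecompositionOptions | None = None) -> pd.DataFrame:
        return rank_sweep(self.t1, self.t2, ranks, options)


class CoupledCPResults:
    """Fitted coupled CP decomposition."""

    def __init__(self, model: CoupledCP, result: CoupledResult):
        self.model = model
        self._result = result

    @property
    def rank(self) -> int:
        return self._result.assumed_rank

    @property
    def reliability(self) -> float:
        return self._result.reliability

    @property
    def residuals(self) -> tuple:
        return self._result.residuals

    @property
    def common_factor(self) -> np.ndarray:
        """The selected estimate of the shared first-mode factor (tensor 1's pick)."""
        return self._result.selected[0].factors[0]

    def factors(self, which: int):
        """Factor matrices [F1, F2, F3] of tensor ``which`` (1 or 2)."""
        return list(self._result.selected[which - 1].factors)

    def amplitudes(self, which: int) -> np.ndarray:
        return self._result.selected[which - 1].amplitudes

    def fittedvalues(self, which: int) -> Tensor3:
        return cp_reconstruct(self._result.selected[which - 1])

    def resid(self, which: int) -> Tensor3:
        t = (self.model.t1, self.model.t2)[which - 1]
        return Tensor3(_data(t) - self.fittedvalues(which).data)

    @property
    def candidate_table(self) -> pd.DataFrame:
        return self._result.candidate_table.table()

    @property
    def selected_labels(self) -> tuple:
        return self._result.selected_labels

    def summary(self) -> str:
        res = self._result
        lines = [
            "Coupled CP decomposition (semi-algebraic, REC PS selection)",
            "=" * 60,
            f"assumed rank:        {res.assumed_rank}",
            f"reliability:         {res.reliability:.2f} %",
            f"selected candidates: {res.selected_labels}",
            f"residual e_rec:      ({res.residuals[0]:.3e}, {res.residuals[1]:.3e})",
            "",
            "Candidate table:",
            res.candidate_table.table().to_string(index=False),
        ]
        return "\n".join(lines)
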