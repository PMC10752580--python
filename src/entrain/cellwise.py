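"""Rolling-window environmental-dependence profile along pseudotime.

Whole-branch %E.V.E. is one number; differentiation rarely depends on the
niche uniformly, so the branch is re-analysed in overlapping windows of
cells ordered by pseudotime. Each window recomputes the gene-pseudotime
covariance, reselects TRAINing genes (optionally reusing the branch-level
selection), rebuilds the design and refits the forest. Windows too small to
satisfy the gene-overlap floor yield a missing E.V.E. rather than aborting,
so profiles degrade gracefully at branch tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ligand_scoring import ActiveLigandSet, build_design, fit_ligand_model
from .training_genes import (TrainingGeneSet, branch_covariance,
                             select_training_genes)
from .types import LigandTargetPrior, TrajectoryBranch

DEFAULT_N_WINDOWS = 100
DEFAULT_WINDOW_FRAC = 0.1
DEFAULT_MIN_WINDOW_CELLS = 30


@dataclass
class WindowProfile:
    """Per-window E.V.E. and top ligands for one branch."""

    frame: pd.DataFrame  # window_index, start, end, mean_pseudotime, eve_percent, top_ligands
    branch: str
    window_size: int
    n_windows: int


def rolling_windows(branch: TrajectoryBranch,
                    n_windows: int = DEFAULT_N_WINDOWS,
                    window_frac: float = DEFAULT_WINDOW_FRAC,
                    min_cells: int = DEFAULT_MIN_WINDOW_CELLS,
                    ) -> list:
    """Build windows of pseudotime-ordered cell indices.

    Cells are sorted by pseudotime (ties by cell id for determinism). The
    window width is ``max(min_cells, ceil(window_frac * n))`` and the
    ``n_windows`` start offsets are evenly spaced over [0, n - width];
    duplicate starts after integer rounding collapse, so at most
    ``n_windows`` windows are returned. Each window is an index array into
    the branch's rows.
    """
    n = branch.n_cells
    if n_windows < 1:
        raise ValidationError("n_windows must be >= 1")
    if min_cells < 3:
        raise ValidationError("min_cells must be >= 3")
    if n < min_cells:
        raise ValidationError(
            f"branch has {n} cells, fewer than the minimum window size "
            f"{min_cells}")
    width = max(min_cells, math.ceil(window_frac * n))
    width = min(width, n)
    order = np.lexsort((np.asarray(branch.cell_ids, dtype=object), branch.tau))
    starts = np.unique(np.round(np.linspace(0, n - width, n_windows)).astype(int))
    return [order[s:s + width] for s in starts]


def windowed_eve(branch: TrajectoryBranch,
                 prior: LigandTargetPrior,
                 active: Union[ActiveLigandSet, Sequence[str]],
                 n_windows: int = DEFAULT_N_WINDOWS,
                 window_frac: float = DEFAULT_WINDOW_FRAC,
                 min_cells: int = DEFAULT_MIN_WINDOW_CELLS,
                 drop_fraction: float = 0.05,
                 metric: str = "covariance",
                 training: Optional[TrainingGeneSet] = None,
                 n_trees: int = 500,
                 mtry: Optional[int] = None,
                 seed: int = 0,
                 top_k: int = 5) -> WindowProfile:
    """E.V.E. profile along pseudotime.

    Pass ``training`` to reuse a branch-level TRAINing-gene selection;
    otherwise genes are reselected inside every window. The same forest seed
    is used for every window, so a single whole-branch window reproduces the
    branch-level fit exactly.
    """
    windows = rolling_windows(branch, n_windows, window_frac, min_cells)
    order = np.lexsort((np.asarray(branch.cell_ids, dtype=object), branch.tau))
    position = np.empty(branch.n_cells, dtype=int)
    position[order] = np.arange(branch.n_cells)
    rows = []
    for w_idx, window in enumerate(windows):
        sub = branch.subset_cells(window)
        record = {
            "window_index": w_idx,
            # start/end are positions in pseudotime-sorted order, end exclusive
            "start": int(position[window[0]]),
            "end": int(position[window[-1]]) + 1,
            "mean_pseudotime": float(sub.tau.mean()),
            "eve_percent": float("nan"),
            "top_ligands": "",
        }
        try:
            cov = branch_covariance(sub, metric=metric)
            tset = training if training is not None else \
                select_training_genes(cov, drop_fraction)
            design = build_design(prior, tset, active, cov)
            model = fit_ligand_model(design, n_trees=n_trees, mtry=mtry,
                                     seed=seed)
            record["eve_percent"] = model.eve_percent
            record["top_ligands"] = ";".join(model.top_ligands(top_k))
        except ValidationError:
            # insufficient overlap / degenerate window: leave E.V.E. missing
            pass
        rows.append(record)
    frame = pd.DataFrame(rows)
    return WindowProfile(frame, branch.label,
                         int(len(windows[0])) if windows else 0, len(windows))
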