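"""Model / Results front end.

:class:`SaxsModel` bundles a structure, an optional experimental dataset
and a configuration; ``fit()`` returns a :class:`SaxsResults` carrying the
estimates, goodness of fit and diagnostics with a ``summary()`` table,
in the style of statistical modeling packages.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from . import fitting
from .config import RunConfig
from .fitting import FitResult, SaxsDataset, read_saxs_dat
from .pipeline import ProfileCalculator
from .scattering import ScatteringProfile
from .structures import Structure, read_pdb

__all__ = ["SaxsModel", "SaxsResults"]


class SaxsModel:
    """Forward SAXS model of a structure, optionally bound to data.

    Parameters
    ----------
    structure:
        The solute. Implicit hydrogens are assigned automatically when the
        structure carries none.
    dataset:
        Experimental (q, I, sigma) curve; required for :meth:`fit`.
    exv_mode:
        'simple' (default), 'fraser' or 'grid' excluded-volume model.
    config:
        Full :class:`RunConfig`; keyword overrides are applied on top.
    """

    def __init__(self, structure: Structure,
                 dataset: Optional[SaxsDataset] = None,
                 exv_mode: Optional[str] = None,
                 config: Optional[RunConfig] = None,
                 **overrides):
        cfg = config or RunConfig()
        if exv_mode is not None:
            overrides["exv_mode"] = exv_mode
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
        self.config = cfg
        self.structure = structure
        self.dataset = dataset
        self._calculator: Optional[ProfileCalculator] = None

    @classmethod
    def from_files(cls, pdb_path, dat_path=None, **kwargs) -> "SaxsModel":
        structure = read_pdb(pdb_path).strip_solvent()
        dataset = read_saxs_dat(dat_path) if dat_path is not None else None
        return cls(structure, dataset, **kwargs)

    @property
    def calculator(self) -> ProfileCalculator:
        if self._calculator is None:
            self._calculator = ProfileCalculator(self.structure, self.config)
        return self._calculator

    @property
    def waters(self):
        return self.calculator.waters

    def profile(self, c: float = 1.0, gamma: float = 1.0) -> ScatteringProfile:
        """Model profile (total + six partials) on the internal q grid."""
        return self.calculator.profile(c=c, gamma=gamma)

    def fit(self, seed: Optional[int] = None) -> "SaxsResults":
        if self.dataset is None:
            raise ValueError("model has no dataset to fit against")
        result = fitting.fit(self.structure, self.dataset,
                             config=self.config, seed=seed,
                             calculator=self.calculator)
        return SaxsResults(self, result)


class SaxsResults:
    """Estimates and diagnostics of a completed fit."""

    def __init__(self, model: SaxsModel, result: FitResult):
        self.model = model
        self._result = result

    # -- estimates ----------------------------------------------------------
    @property
    def params(self) -> dict:
        p = {"a": self._result.a, "b": self._result.b, "c": self._result.c}
        if self._result.d is not None:
            p["d"] = self._result.d
        return p

    @property
    def chi2_reduced(self) -> float:
        return self._result.chi2_reduced

    @property
    def nu(self) -> int:
        return self._result.nu

    @property
    def fittedvalues(self) -> np.ndarray:
        return self._result.fitted

    @property
    def resid(self) -> np.ndarray:
        """Uncertainty-normalized residuals (I - I_fit) / sigma."""
        return self._result.residuals

    @property
    def converged(self) -> bool:
        return self._result.converged

    def summary(self) -> str:
        r = self._result
        data = r.data
        lines = [
            "SAXS profile fit",
            "=" * 46,
            f"{'excluded-volume model':<28s}{r.exv_mode:>18s}",
            f"{'data points':<28s}{len(data):>18d}",
            f"{'q range [1/A]':<28s}"
            f"{f'{data.q.min():.4g} - {data.q.max():.4g}':>18s}",
            f"{'free parameters':<28s}{r.n_parameters:>18d}",
            f"{'degrees of freedom (nu)':<28s}{r.nu:>18d}",
            "-" * 46,
            f"{'a  (linear scale)':<28s}{r.a:>18.6g}",
            f"{'b  (background)':<28s}{r.b:>18.6g}",
            f"{'c  (hydration scale)':<28s}{r.c:>18.6g}",
        ]
        if r.d is not None:
            lines.append(f"{'d  (exv scale gamma)':<28s}{r.d:>18.6g}")
        lines += [
            "-" * 46,
            f"{'reduced chi-square':<28s}{r.chi2_reduced:>18.6g}",
        ]
        return "\n".join(lines)

    def plot(self, path=None):
        """Fit and residual panels; saves to ``path`` or returns the figure."""
        import matplotlib
        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        data = self._result.data
        fig, (ax1, ax2) = plt.subplots(
            2, 1, sharex=True, figsize=(6, 6),
            gridspec_kw={"height_ratios": [3, 1]})
        ax1.errorbar(data.q, data.intensity, yerr=data.sigma, fmt=".",
                     ms=3, alpha=0.6, label="data")
        ax1.plot(data.q, self.fittedvalues, "-", lw=1.5, label="model")
        ax1.set_yscale("log")
        ax1.set_ylabel("I(q)")
        ax1.legend()
        ax2.axhline(0.0, color="k", lw=0.8)
        ax2.plot(data.q, self.resid, ".", ms=3)
        ax2.set_xlabel("q [1/A]")
        ax2.set_ylabel(r"(I - I$_{fit}$)/$\sigma$")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return fig
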