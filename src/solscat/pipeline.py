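"""End-to-end profile calculation: structure -> grid -> hydration ->
excluded volume -> histograms -> partial intensity curves.

:class:`ProfileCalculator` performs all expensive work (grid expansion,
water placement, pair binning, per-class-pair structure curves) once at
construction; evaluating a profile for given hydration scale ``c`` and
excluded-volume scale ``gamma`` is then cheap algebra, which is what makes
the reduced-chi^2 fit fast.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .config import RunConfig
from .excluded_volume import (ExcludedVolumeModel, fraser_model, grid_model,
                              simple_model)
from .formfactors import FormFactorRegistry, load_volume_table
from .grid import build_grid
from .hydration import WaterSet, place_waters
from .scattering import (CategoryCurves, ScattererSet, ScatteringProfile,
                         assemble_profile, build_histogram, cross_histogram,
                         default_q_grid)
from .structures import Structure, assign_implicit_hydrogens

__all__ = ["ProfileCalculator"]


class ProfileCalculator:
    """Forward scattering model of one structure under one configuration.

    The input structure is used as-is when it already carries implicit
    hydrogen counts or explicit hydrogens; otherwise the bundled residue
    table assigns implicit hydrogens first.
    """

    def __init__(self, structure: Structure, config: Optional[RunConfig] = None):
        self.config = config or RunConfig()
        structure.require_atoms()
        if (not structure.has_explicit_hydrogens
                and all(a.n_implicit_h == 0 for a in structure)):
            structure = assign_implicit_hydrogens(structure)
        self.structure = structure
        cfg = self.config
        self.q = default_q_grid(cfg.q_min, cfg.q_max, cfg.n_q)
        self.registry = FormFactorRegistry()

        self.grid = build_grid(structure, cell_width=cfg.cell_width)
        self.grid.expand_atoms()

        if cfg.hydrate:
            self.waters = place_waters(self.grid, structure,
                                       cfg.hydration_params())
        else:
            self.waters = WaterSet(np.zeros((0, 3)))

        self.exv_model = self._build_exv()
        if self.exv_model is not None:
            self.exv_model.register_form_factors(self.registry)

        self._curves = self._build_curves()

    # -- construction helpers ----------------------------------------------
    def _build_exv(self) -> Optional[ExcludedVolumeModel]:
        cfg = self.config
        if cfg.exv_mode == "simple":
            return simple_model(self.structure, self.grid, rho0=cfg.rho0,
                                r_bar=cfg.simple_radius)
        if cfg.exv_mode == "fraser":
            mode = ("explicit" if self.structure.has_explicit_hydrogens
                    else "implicit")
            table = load_volume_table(cfg.volume_table, mode)
            return fraser_model(self.structure, table, rho0=cfg.rho0)
        return grid_model(self.grid, self.structure, rho0=cfg.rho0,
                          fit_surface=cfg.fit_surface)

    def _build_curves(self) -> Dict[str, Optional[CategoryCurves]]:
        cfg = self.config
        atoms = ScattererSet.from_structure(self.structure)
        sets = {"a": atoms}
        if len(self.waters):
            sets["w"] = ScattererSet.from_waters(self.waters)
        if self.exv_model is not None:
            sets["x"] = ScattererSet.from_excluded_volume(self.exv_model)

        def curves_for(hist):
            return CategoryCurves(hist, self.q, self.registry)

        bw, wt = cfg.bin_width, cfg.weighted_bins
        curves: Dict[str, Optional[CategoryCurves]] = {
            k: None for k in ("aa", "aw", "ww", "ax", "xx", "xw")}
        curves["aa"] = curves_for(build_histogram(atoms, bw, wt))
        if "w" in sets:
            curves["ww"] = curves_for(build_histogram(sets["w"], bw, wt))
            curves["aw"] = curves_for(cross_histogram(atoms, sets["w"], bw, wt))
        if "x" in sets:
            curves["xx"] = curves_for(build_histogram(sets["x"], bw, wt))
            curves["ax"] = curves_for(cross_histogram(atoms, sets["x"], bw, wt))
            if "w" in sets:
                curves["xw"] = curves_for(
                    cross_histogram(sets["x"], sets["w"], bw, wt))
        self._sets = sets
        return curves

    # -- evaluation ---------------------------------------------------------
    @property
    def gamma_bounds(self):
        if self.exv_model is None or self.exv_model.gamma_bounds is None:
            return None
        return self.exv_model.gamma_bounds

    def profile(self, c: float = 1.0, gamma: float = 1.0) -> ScatteringProfile:
        """Total + partial intensities on the internal q grid."""
        return assemble_profile(self._curves, self.q, c=c, gamma=gamma,
                                exv_model=self.exv_model)

    def intensity(self, c: float = 1.0, gamma: float = 1.0) -> np.ndarray:
        return self.profile(c=c, gamma=gamma).I_total
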