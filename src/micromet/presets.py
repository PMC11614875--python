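"""Reduced-scale configuration presets spanning the outcome repertoire.

Three presets share one reduced tissue patch (~500 cells, 10 simulated
days) and differ only in immune strength, reproducing the qualitative
outcome repertoire: a low immune response lets the colony escape toward
the domain's carrying capacity (NC), a moderate response partially
eliminates it (MC), and a high response clears it before day 10 (SC).

The reduced patch uses coarser mechanics/diffusion substeps (0.5 min); the
implicit field solver is unconditionally stable and, at these decay and
motility scales, the trajectories are insensitive to the refinement (see
docs/methods.md).
"""

from __future__ import annotations

from .config import WorldConfig
from .errors import ConfigurationError

__all__ = ["preset_config", "PRESET_LEVELS"]

PRESET_LEVELS = ("low", "moderate", "high")


def _reduced_base(seed: int) -> WorldConfig:
    cfg = WorldConfig(seed=seed)
    cfg.domain_size = 380.0
    cfg.voxel_size = 20.0
    cfg.dt_diffusion = 1.0
    cfg.dt_mechanics = 1.0
    cfg.dt_phenotype = 6.0
    cfg.initial_cancer = 5
    return cfg


def preset_config(level: str, seed: int = 0) -> WorldConfig:
    """Reduced-domain preset: level in {'low', 'moderate', 'high'}."""
    if level not in PRESET_LEVELS:
        raise ConfigurationError(f"unknown preset {level!r}; choose from {PRESET_LEVELS}")
    cfg = _reduced_base(seed)
    if level == "low":
        # negligible resident immunity, no recruitment: tumor escape
        cfg.initial_macrophages = 2
        cfg.initial_dcs = 1
        cfg.recruit_m.r_recruit = 0.0
        cfg.recruit_d.r_recruit = 0.0
        cfg.rates.r_phag = 0.005
        cfg.rates.r_attach_dc = 0.005
    elif level == "moderate":
        # weak resident phagocytes and a slow, small lymph-node output: the
        # delayed response prunes the colony but cannot clear it by day 10
        cfg.initial_macrophages = 12
        cfg.initial_dcs = 6
        cfg.recruit_m.r_recruit = 1.0e-8
        cfg.recruit_d.r_recruit = 0.4e-8
        cfg.rates.r_phag = 0.04
        cfg.rates.r_attach_dc = 0.012
        cfg.rates.r_leave = 8e-4
        cfg.ln.pi_T = 1.7e-3
        cfg.ln.kappa_T = 1.2e-4
        cfg.ln.tau_T = 1260.0
    else:  # high
        # strong resident immunity, recruitment and T-cell production: clearance
        cfg.initial_macrophages = 15
        cfg.initial_dcs = 6
        cfg.recruit_m.r_recruit = 2e-8
        cfg.recruit_d.r_recruit = 1e-8
        cfg.rates.r_phag = 0.1
        cfg.rates.r_attach_dc = 0.05
        cfg.rates.r_leave = 3e-3
        cfg.rates.r_attach_cd8 = 0.1
        cfg.rates.T_attach = 30.0
        cfg.ln.pi_T = 5e-3
        cfg.ln.kappa_T = 5e-4
        cfg.ln.tau_DC = 120.0
        cfg.ln.tau_T = 360.0
    return cfg
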