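"""Published stoichiometric parameter sets used as verification fixtures.

Two reference strains are shipped: a recombinant *Escherichia coli* with a
parabolic maintenance-vs-biomass law and a *Saccharomyces cerevisiae* with a
linear one.  ``k1``/``t_i`` belong to the offline identification stage and
are not part of the published online parameter set; they are stored as zero
here.  The *E. coli* parabola has no real root, so its threshold
``X_specific`` is its stationary point (flagged on the model).
"""

from .model_core import MaintenanceModel, StrainParameters
from .stage_a import compute_x_specific

__all__ = ["ECOLI", "YEAST", "ecoli_maintenance", "yeast_maintenance"]


def ecoli_maintenance() -> MaintenanceModel:
    k2, k1, k0 = 7.2e-5, -2.9625e-3, 4.27047e-2
    xs = compute_x_specific(k2, k1, k0, degree=2)
    return MaintenanceModel(
        k_beta2=k2,
        k_beta1=k1,
        k_beta0=k0,
        x_specific=xs.value,
        degree=2,
        x_specific_from_stationary_point=xs.from_stationary_point,
    )


def yeast_maintenance() -> MaintenanceModel:
    k1, k0 = 2.3851e-3, -1.5014e-2
    xs = compute_x_specific(0.0, k1, k0, degree=1)
    return MaintenanceModel(
        k_beta2=0.0, k_beta1=k1, k_beta0=k0, x_specific=xs.value, degree=1
    )


ECOLI = StrainParameters(
    alpha=1.01,
    k1=0.0,
    t_i=0.0,
    k_exp=0.4,
    maintenance=ecoli_maintenance(),
    strain_label="Escherichia coli",
)

YEAST = StrainParameters(
    alpha=1.35,
    k1=0.0,
    t_i=0.0,
    k_exp=0.4,
    maintenance=yeast_maintenance(),
    strain_label="Saccharomyces cerevisiae",
)
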