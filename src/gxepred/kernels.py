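"""Observation-level model kernels for the Bayesian G x E models.

Given a trial design (one genotype and one environment per observation),
the genetic relationship matrix H and optionally the enviromic kernel
Omega, the four model components use:

* KE  = ZE ZE'         -- environment indicator kernel (entries 0/1)
* Kg  = Zg H Zg'       -- genetic kernel
* KgE = Kg (.) KE      -- unstructured G x E deviation kernel
* KW  = ZE Omega ZE'   -- enviromic environment kernel
* KgW = Kg (.) KW      -- reaction-norm (predictable G x E) kernel

with (.) the Hadamard product and Z the incidence matrices implied by the
design labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ModelDesign", "KernelSet", "build_kernels", "MODEL_COMPONENTS"]

#: random components used by each model structure, in sampling order; the
#: reaction-norm models carry both the iid environment effect E and the
#: enviromic main effect W (the predictable part of environmental
#: variation), plus the genotype-specific reaction norm gW
MODEL_COMPONENTS = {
    "MM": ("E", "g"),
    "MDs": ("E", "g", "gE"),
    "RNMM": ("E", "W", "g", "gW"),
    "RNMDs": ("E", "W", "g", "gE", "gW"),
}


@dataclass
class ModelDesign:
    """Observation index: genotype and environment label per row."""

    genotype: pd.Series
    environment: pd.Series

    def __post_init__(self) -> None:
        if len(self.genotype) != len(self.environment):
            raise ValueError("genotype/environment length mismatch")
        self.genotype = self.genotype.reset_index(drop=True)
        self.environment = self.environment.reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ModelDesign":
        return cls(genotype=frame["genotype"].astype(str),
                   environment=frame["environment"].astype(str))

    def __len__(self) -> int:
        return len(self.genotype)


@dataclass
class KernelSet:
    """Dense observation-level kernels keyed by model component name.

    ``geno_idx``/``env_idx`` map observations onto the unique genotype and
    environment labels; ``H_sub`` is the genotype-level relationship block.
    The sampler uses these to build eigenbases cheaply (the environment and
    G x E deviation kernels are block-diagonal by environment, the genetic
    kernel has rank at most the number of genotypes).
    """

    design: ModelDesign
    kernels: dict[str, np.ndarray] = field(default_factory=dict)
    geno_idx: np.ndarray | None = None
    env_idx: np.ndarray | None = None
    H_sub: np.ndarray | None = None
    Omega_sub: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.design)

    def for_model(self, model_type: str) -> dict[str, np.ndarray]:
        try:
            names = MODEL_COMPONENTS[model_type]
        except KeyError:
            raise ValueError(f"unknown model type {model_type!r}") from None
        missing = [c for c in names if c not in self.kernels]
        if missing:
            raise ValueError(
                f"kernel(s) {missing} unavailable for {model_type}; "
                "reaction-norm models need an enviromic kernel")
        return {c: self.kernels[c] for c in names}


def _lookup(matrix: pd.DataFrame, labels: pd.Series, what: str) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(matrix.index)}
    try:
        pos = np.array([index[lab] for lab in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"{what} label {exc.args[0]!r} not found in "
                         f"{what} relationship matrix") from None
    return pos


def build_kernels(design: ModelDesign, H: pd.DataFrame,
                  Omega: pd.DataFrame | None = None) -> KernelSet:
    """Assemble the observation-level kernels for a trial design.

    ``Omega`` may be an :class:`~gxepred.envirotyping.EnviromicKernel` or a
    plain labelled square frame; when omitted only the MM/MDs kernels are
    produced.
    """
    if hasattr(Omega, "matrix"):
        Omega = Omega.matrix
    gi = _lookup(H, design.genotype, "genotype")
    Kg = H.to_numpy(dtype=float)[np.ix_(gi, gi)]
    env = design.environment.to_numpy()
    KE = (env[:, None] == env[None, :]).astype(float)
    kernels = {"E": KE, "g": Kg, "gE": Kg * KE}
    tg = pd.unique(design.genotype)
    te = pd.unique(design.environment)
    Omega_sub = None
    if Omega is not None:
        ei = _lookup(Omega, design.environment, "environment")
        KW = Omega.to_numpy(dtype=float)[np.ix_(ei, ei)]
        kernels["W"] = KW
        kernels["gW"] = Kg * KW
        Omega_sub = Omega.loc[list(te), list(te)].to_numpy(dtype=float)
    geno_idx = design.genotype.map(
        {g: i for i, g in enumerate(tg)}).to_numpy()
    env_idx = design.environment.map(
        {e: i for i, e in enumerate(te)}).to_numpy()
    H_sub = H.loc[list(tg), list(tg)].to_numpy(dtype=float)
    return KernelSet(design=design, kernels=kernels, geno_idx=geno_idx,
                     env_idx=env_idx, H_sub=H_sub, Omega_sub=Omega_sub)
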