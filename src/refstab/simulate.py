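"""Seeded generator of synthetic Ct datasets with known ground truth.

The generative model mirrors what the stability statistics assume about real
RT-qPCR panels, on the cycle scale::

    Ct[g, s, r] = baseline[g] + shift[g, s] + load[s] + noise[g, s, r]

* ``baseline`` — per-gene expression level (cycles; lower = more abundant);
* ``shift``   — tissue-dependent expression change, Normal(0, instability_sd[g]),
  drawn per gene x sample, or per gene x group when groups are declared (an
  "unstable" gene then means tissue-dependent expression);
* ``load``    — shared per-sample effect, Normal(0, loading_sd): template input
  and RT differences that hit every gene alike and that normalization must cancel;
* ``noise``   — technical replicate noise, Normal(0, tech_sd).

The per-gene instability SDs are the ground truth that stability rankings
should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ct_data import CtMatrix, CtValidationError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "generate_ct_dataset",
    "spike_target",
]

#: Default 11-gene candidate panel: (gene, baseline Ct, instability SD in cycles).
#: Baselines span ~17-25 cycles, the range typical of abundant housekeeping
#: transcripts (rRNA at the bottom, tubulin at the top). Instability SDs spread
#: from clearly stable (~0.15) to clearly tissue-dependent (~1.2).
DEFAULT_PANEL: tuple[tuple[str, float, float], ...] = (
    ("RPL4", 21.0, 0.15),
    ("RPL18", 21.5, 0.15),
    ("HIS3", 20.5, 0.20),
    ("TUA3", 25.0, 0.25),
    ("SAMDC", 23.0, 1.20),
    ("TIP41", 24.5, 0.35),
    ("UGPase", 22.5, 0.50),
    ("18S", 17.0, 0.90),
    ("GAPDH", 20.0, 0.45),
    ("PIP2", 19.5, 1.00),
    ("ACT", 21.0, 0.40),
)

#: Default 23-sample design: five fruit stages, seven floral tissues, three
#: ovule and three seed stages, five vegetative tissues.
DEFAULT_SAMPLE_GROUPS: tuple[tuple[str, str], ...] = (
    ("Fr1", "Fruits"),
    ("Fr2", "Fruits"),
    ("Fr3", "Fruits"),
    ("Fr4", "Fruits"),
    ("Fr5", "Fruits"),
    ("If", "Floral tissues"),
    ("Fl", "Floral tissues"),
    ("Pe", "Floral tissues"),
    ("An", "Floral tissues"),
    ("St", "Floral tissues"),
    ("Fi", "Floral tissues"),
    ("Ca", "Floral tissues"),
    ("Ov1", "Ovules and seeds"),
    ("Ov2", "Ovules and seeds"),
    ("Ov3", "Ovules and seeds"),
    ("Sd1", "Ovules and seeds"),
    ("Sd2", "Ovules and seeds"),
    ("Sd3", "Ovules and seeds"),
    ("Rt", "Vegetative tissues"),
    ("Yst", "Vegetative tissues"),
    ("Mst", "Vegetative tissues"),
    ("Yl", "Vegetative tissues"),
    ("Ml", "Vegetative tissues"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of one synthetic Ct dataset."""

    gene_ids: tuple[str, ...]
    baseline_ct: tuple[float, ...]
    instability_sd: tuple[float, ...]
    sample_ids: tuple[str, ...]
    groups: tuple[tuple[str, str], ...] | None = None  # (sample, group) pairs
    n_replicates: int = 4
    loading_sd: float = 1.0
    tech_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        G = len(self.gene_ids)
        if len(self.baseline_ct) != G or len(self.instability_sd) != G:
            raise CtValidationError("per-gene parameter lengths do not match gene_ids")
        if self.n_replicates < 1:
            raise CtValidationError("n_replicates must be >= 1")
        if (
            min(self.instability_sd, default=0.0) < 0
            or self.loading_sd < 0
            or self.tech_sd < 0
        ):
            raise CtValidationError("all noise SDs must be >= 0")
        if self.groups is not None:
            labelled = {s for s, _ in self.groups}
            if labelled != set(self.sample_ids):
                raise CtValidationError("groups must label exactly the sample_ids")

    @property
    def group_map(self) -> dict[str, str] | None:
        return dict(self.groups) if self.groups is not None else None


@dataclass
class GroundTruth:
    """Realized latent variables of one generated dataset.

    ``instability_sd`` orders genes by true stability (ascending = most
    stable first); ``shifts`` and ``loading`` are the realized tissue and
    loading effects; ``target_profile`` is filled by :func:`spike_target`.
    """

    config: SyntheticConfig
    instability_sd: dict[str, float]
    shifts: pd.DataFrame  # genes x samples, cycles
    loading: pd.Series  # per sample, cycles
    target_profile: pd.Series | None = None

    def true_order(self) -> list[str]:
        return sorted(self.instability_sd, key=lambda g: self.instability_sd[g])

    def write(self, path: str | Path) -> None:
        payload = {
            "seed": self.config.seed,
            "instability_sd": {g: float(v) for g, v in self.instability_sd.items()},
            "loading": {s: float(v) for s, v in self.loading.items()},
            "shifts": {
                g: [float(v) for v in self.shifts.loc[g]] for g in self.shifts.index
            },
        }
        if self.target_profile is not None:
            payload["target_profile"] = {
                s: float(v) for s, v in self.target_profile.items()
            }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default dataset design: 11 genes x 23 samples x 4 replicates with
    baselines over 17-25 cycles and four declared tissue groups."""
    genes, baselines, sds = zip(*DEFAULT_PANEL)
    samples = tuple(s for s, _ in DEFAULT_SAMPLE_GROUPS)
    cfg = SyntheticConfig(
        gene_ids=genes,
        baseline_ct=baselines,
        instability_sd=sds,
        sample_ids=samples,
        groups=DEFAULT_SAMPLE_GROUPS,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def generate_ct_dataset(config: SyntheticConfig) -> tuple[CtMatrix, GroundTruth]:
    """Draw one dataset; the same config (including seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    G, S, R = len(config.gene_ids), len(config.sample_ids), config.n_replicates
    baseline = np.asarray(config.baseline_ct)[:, None]
    inst = np.asarray(config.instability_sd)[:, None]
    if config.groups is not None:
        gmap = config.group_map
        labels = [gmap[s] for s in config.sample_ids]
        uniq = list(dict.fromkeys(labels))
        per_group = rng.normal(0.0, 1.0, (G, len(uniq))) * inst
        col = np.array([uniq.index(lab) for lab in labels])
        shift = per_group[:, col]
    else:
        shift = rng.normal(0.0, 1.0, (G, S)) * inst
    load = rng.normal(0.0, config.loading_sd, S)
    noise = rng.normal(0.0, config.tech_sd, (G, S, R))
    ct = baseline[:, :, None] + shift[:, :, None] + load[None, :, None] + noise
    m = CtMatrix(list(config.gene_ids), list(config.sample_ids), ct, config.group_map)
    truth = GroundTruth(
        config=config,
        instability_sd=dict(zip(config.gene_ids, map(float, config.instability_sd))),
        shifts=pd.DataFrame(shift, index=list(config.gene_ids), columns=list(config.sample_ids)),
        loading=pd.Series(load, index=list(config.sample_ids), name="loading"),
    )
    return m, truth


def spike_target(
    m: CtMatrix,
    truth: GroundTruth,
    profile: Mapping[str, float] | Sequence[float] | pd.Series,
    name: str = "TARGET",
    baseline_ct: float = 24.0,
    tech_sd: float | None = None,
) -> tuple[CtMatrix, GroundTruth]:
    """Append a target gene whose Ct encodes a programmed log2 expression profile.

    The target shares the dataset's realized per-sample loading effects and
    technical-noise level: ``Ct = baseline - profile + load + noise`` (one
    extra log2 unit of expression = one cycle earlier). Draws are seeded from
    the dataset's own seed, so spiking is reproducible.
    """
    if name in m.genes:
        raise CtValidationError(f"gene {name!r} already present")
    if isinstance(profile, pd.Series):
        prof = profile.reindex(m.samples)
        if prof.isna().any():
            raise CtValidationError("profile does not cover all samples")
    elif isinstance(profile, Mapping):
        missing = [s for s in m.samples if s not in profile]
        if missing:
            raise CtValidationError(f"profile missing samples: {missing}")
        prof = pd.Series({s: float(profile[s]) for s in m.samples})
    else:
        vals = list(profile)
        if len(vals) != len(m.samples):
            raise CtValidationError("profile length does not match sample count")
        prof = pd.Series(vals, index=m.samples, dtype=float)
    sd = truth.config.tech_sd if tech_sd is None else tech_sd
    rng = np.random.default_rng([truth.config.seed, 0x5EED])
    noise = rng.normal(0.0, sd, (len(m.samples), m.n_replicates))
    ct_target = (
        baseline_ct
        - prof.to_numpy()[:, None]
        + truth.loading.loc[m.samples].to_numpy()[:, None]
        + noise
    )
    ct = np.concatenate([m.ct, ct_target[None, :, :]], axis=0)
    out = CtMatrix(list(m.genes) + [name], list(m.samples), ct, m.groups)
    new_truth = GroundTruth(
        config=truth.config,
        instability_sd=dict(truth.instability_sd),
        shifts=truth.shifts,
        loading=truth.loading,
        target_profile=prof.rename(name),
    )
    return out, new_truth
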