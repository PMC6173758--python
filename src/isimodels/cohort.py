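"""Synthetic spike-train cohorts emulating the study's recording scale.

The study conditions are 26 recordings of 2000 spikes each (85–257 s),
split between exponential-shaped ISI distributions (fast/slow release-rate
ratio near 2) and L-shaped distributions (ratio up to roughly 10x), with a
majority of recordings carrying positive serial correlation.  The cohort
generator reproduces that structure from ground-truth generative models —
iid renewal sampling, slow two-state switching (which adds the positive
SRC(1)), or depletion-replenishment — and records every parameter in a
manifest so regeneration is bit-identical and every downstream analysis
can be tested against known truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .depletion import DepletionRefractory, DepletionSourceParams, simulate_depletion
from .renewal import (
    RefractoryParams,
    RenewalModel,
    TwoExpMixExcitation,
    sample_isis,
)
from .spiketrain import ISISequence, SpikeTrain, write_spike_file
from .switching import SwitchingParams, simulate_switching

__all__ = ["CohortSpec", "CohortManifest", "make_cohort", "make_poisson_train"]

# per-dataset jitter pools, anchored to the plausible physiological regime:
# refractory 2 + 2 ms, fast release wait tens of ms, slow switching
_T_ABS = 2.0
_TAU_REL = 2.0
_K_SF_SLOW = 1e-4  # 1/ms; switching time scale of many ISIs
_MEAN_ISI_RANGE = (50.0, 120.0)  # ms -> 2000 spikes span 100-240 s
# fast/slow rate-ratio pools: at this refractory scale the L-shape boundary
# ell = 1 sits near ratio 2, so the exponential-shaped pool stays just below
# it (fitted ratios near 2) and the L-shaped pool near one order of magnitude
_RATIO_EXP = (1.4, 1.9)
_RATIO_L = (6.0, 12.0)
_P_FAST_RANGE = (0.4, 0.6)


@dataclass(frozen=True)
class CohortSpec:
    n_datasets: int = 26
    n_spikes_per_dataset: int = 2000
    shape_mix: float = 0.5  # fraction of L-shaped datasets
    serial_mode: str = "switching"  # {"renewal", "switching", "depletion"}
    seed: int = 0

    def __post_init__(self):
        if self.n_datasets < 1 or self.n_spikes_per_dataset < 2:
            raise ValueError("counts must be >= 1 (and >= 2 spikes)")
        if not 0 <= self.shape_mix <= 1:
            raise ValueError("shape_mix must lie in [0, 1]")
        if self.serial_mode not in ("renewal", "switching", "depletion"):
            raise ValueError(f"unknown serial_mode {self.serial_mode!r}")


@dataclass
class CohortManifest:
    spec: CohortSpec
    datasets: list  # per-dataset dicts: id, generator, params, seed, file

    def to_json(self) -> str:
        return json.dumps(
            {"spec": asdict(self.spec), "datasets": self.datasets}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortManifest":
        d = json.loads(text)
        return cls(spec=CohortSpec(**d["spec"]), datasets=d["datasets"])


def _dataset_params(rng, l_shaped: bool, mode: str) -> dict:
    """Draw one dataset's ground-truth parameters.

    ``tau_fast`` is solved so the realized mean ISI hits the target: for
    iid renewal sampling the mixture mean applies, while for continuous
    switching the spike rate is the time-weighted average of the per-mode
    rates (the fast mode initiates disproportionately many intervals), so
    the harmonic relation 1/m = p/(tau_fast+r) + (1-p)/(ratio*tau_fast+r)
    is solved instead.
    """
    mean_isi = rng.uniform(*_MEAN_ISI_RANGE)
    ratio = rng.uniform(*(_RATIO_L if l_shaped else _RATIO_EXP))
    p_fast = rng.uniform(*_P_FAST_RANGE)
    r = _T_ABS + _TAU_REL
    if mode == "switching":
        from scipy.optimize import brentq

        def excess(tau_fast):
            return (
                p_fast / (tau_fast + r)
                + (1 - p_fast) / (ratio * tau_fast + r)
                - 1.0 / mean_isi
            )

        tau_fast = brentq(excess, 1e-3, 10 * mean_isi)
    else:
        tau_fast = (mean_isi - r) / (p_fast + (1 - p_fast) * ratio)
    return dict(
        l_shaped=l_shaped,
        target_mean_isi=mean_isi,
        rate_ratio=ratio,
        p_fast=p_fast,
        tau_fast=tau_fast,
        tau_slow=tau_fast * ratio,
        t_abs=_T_ABS,
        tau_rel=_TAU_REL,
    )


def _generate_dataset(mode: str, params: dict, n_isis: int, seed: int) -> ISISequence:
    if mode == "renewal":
        model = RenewalModel(
            refractory=RefractoryParams(t_abs=params["t_abs"], tau_rel=params["tau_rel"]),
            excitation=TwoExpMixExcitation(
                p=params["p_fast"],
                lambda_e1=1.0 / params["tau_fast"],
                lambda_e2=1.0 / params["tau_slow"],
            ),
        )
        return ISISequence(sample_isis(model, n_isis, seed))
    if mode == "switching":
        sw = SwitchingParams.from_p_fast(
            k_sf=_K_SF_SLOW,
            p_fast=params["p_fast"],
            tau_fast=params["tau_fast"],
            tau_slow=params["tau_slow"],
            t_abs=params["t_abs"],
            tau_rel=params["tau_rel"],
        )
        return simulate_switching(sw, n_isis, seed, record_switches=False).isis
    # depletion mode: a weakly depleting source tuned to the target rate
    excitation_mean = params["target_mean_isi"] - params["t_abs"] - params["tau_rel"]
    n_max = 4.0
    src = DepletionSourceParams(
        n_max=n_max, p_depl=1.0 / (n_max * excitation_mean), tau_repl=2.5
    )
    refr = DepletionRefractory(t_dead=params["t_abs"], t_rel=params["tau_rel"])
    # the coarse step is adequate here (per-step release probability ~1e-4)
    res = simulate_depletion([src], refr, n_isis, seed, dt=0.01)
    return res.isis


def make_cohort(spec: CohortSpec, out_dir=None):
    """Generate a cohort of spike trains with a ground-truth manifest.

    Returns ``(datasets, manifest)`` where ``datasets`` is a list of
    :class:`SpikeTrain`.  If ``out_dir`` is given, one spike file per
    dataset plus ``manifest.json`` and a ``README.txt`` are written there.
    """
    root = np.random.SeedSequence(spec.seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    data_seeds = root.spawn(1)[0].generate_state(spec.n_datasets) % (2**31 - 1)

    n_l = round(spec.shape_mix * spec.n_datasets)
    labels = np.array([True] * n_l + [False] * (spec.n_datasets - n_l))
    param_rng.shuffle(labels)

    datasets = []
    records = []
    for i in range(spec.n_datasets):
        params = _dataset_params(param_rng, bool(labels[i]), spec.serial_mode)
        isis = _generate_dataset(
            spec.serial_mode, params, spec.n_spikes_per_dataset - 1, int(data_seeds[i])
        )
        train = isis.to_spike_train()
        datasets.append(train)
        records.append(
            dict(
                id=f"synthetic_{i:03d}",
                generator=spec.serial_mode,
                params=params,
                seed=int(data_seeds[i]),
                file=None,
            )
        )
    manifest = CohortManifest(spec=spec, datasets=records)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, train in zip(records, datasets):
            fname = f"{rec['id']}.txt"
            write_spike_file(train, out_dir / fname)
            rec["file"] = fname
        (out_dir / "manifest.json").write_text(manifest.to_json())
        (out_dir / "README.txt").write_text(
            "Synthetic spontaneous spike-train cohort (one timestamp in ms per\n"
            "line per file). Ground-truth generator parameters and seeds are\n"
            "recorded in manifest.json; regenerating from the manifest is\n"
            "bit-identical.\n"
        )
    return datasets, manifest


def regenerate_from_manifest(manifest: CohortManifest):
    """Rebuild the cohort's spike trains exactly from a manifest."""
    spec = manifest.spec
    datasets = []
    for rec in manifest.datasets:
        isis = _generate_dataset(
            rec["generator"],
            rec["params"],
            spec.n_spikes_per_dataset - 1,
            int(rec["seed"]),
        )
        datasets.append(isis.to_spike_train())
    return datasets


def make_poisson_train(rate: float, duration: float, seed) -> SpikeTrain:
    """Homogeneous Poisson spike train on [0, duration] (rate in 1/ms,
    duration in ms): exponential waits at constant probability rate."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(seed)
    # draw in blocks until the horizon is passed
    times = []
    t = 0.0
    block = max(int(rate * duration * 1.25) + 64, 64)
    while t <= duration:
        isis = rng.exponential(1.0 / rate, size=block)
        cum = t + np.cumsum(isis)
        times.append(cum)
        t = cum[-1]
    all_times = np.concatenate(times)
    return SpikeTrain(all_times[all_times <= duration])
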