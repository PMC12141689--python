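"""Synthetic-cohort generator.

Generates ground-truth hemispheric sensitivities, trial-level ERP epochs with
planted components and artifacts, and molecular covariates (gene-expression
levels with batch structure, promoter CpG methylation beta-values) with a
configurable population correlation to the true laterality index.

Model
-----
Each subject has a nonnegative total motion-direction sensitivity T (Gamma)
split between hemispheres by an allocation fraction pi ~ Beta(mu*kappa,
(1-mu)*kappa) drawn per group:

    S_R_true = -T * (1 - pi)      (right-hemisphere sensitivity, uV;
    S_L_true = -T * pi             negative = sensitive)
    LI_true  = S_R_true - S_L_true = T * (2*pi - 1)

so pi < 0.5 gives right-hemisphere specialization (LI < 0).  Because T is
shared, S_R and S_L are negatively correlated across subjects whenever the
allocation has variance — the inverse interhemispheric structure the
analysis probes.  The Gamma mean is derived from the configured group mean
LI: E[T] = group_mean / (2*mu - 1).

Trial waveforms are sums of Gaussian-in-time component kernels on the
component's electrode set plus mixed white/pink noise.  Component amplitudes
are expressed as *measured* window means: each kernel is rescaled by the
numerically computed gain of the default measurement chain (baseline
correction, zero-phase low-pass, inclusive window mean), which makes the
noise-free generator -> pipeline round trip exact to floating point.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import CONDITIONS, SimulationConfig
from .epochs import Epochs
from .layout import ChannelLayout
from .preprocess import lowpass_array

TRUTH_COLUMNS = ["subject", "group", "handedness", "sex",
                 "S_R_true", "S_L_true", "LI_true"]


def _subject_rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(stream, index)))


# --------------------------------------------------------------------- truth
def simulate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-subject latent sensitivities and demographics.

    Returns a frame with columns subject, group, handedness, sex,
    S_R_true, S_L_true, LI_true.  Deterministic given config.seed.
    """
    rng = _subject_rng(config.seed, 0)
    rows = []
    sid = 0
    for group, n in config.n_per_group.items():
        mu, kappa = config.allocation_params[group]
        if not 0.0 < mu < 1.0:
            raise ValueError("allocation mean must be in (0, 1)")
        if abs(2 * mu - 1) < 1e-12 and config.group_means[group] != 0:
            raise ValueError(
                f"group {group}: allocation mean 0.5 cannot target a "
                "nonzero mean LI")
        mean_t = (config.group_means[group] / (2 * mu - 1)
                  if config.group_means[group] != 0 else
                  abs(config.group_means[group]))
        if mean_t < 0:
            raise ValueError(
                f"group {group}: group mean {config.group_means[group]} "
                "inconsistent with allocation mean (implies negative total "
                "sensitivity)")
        sd_t = config.sensitivity_scale
        if sd_t > 0 and mean_t > 0:
            shape = (mean_t / sd_t) ** 2
            scale = sd_t ** 2 / mean_t
            t = rng.gamma(shape, scale, size=n)
        else:
            t = np.full(n, mean_t)
        if np.isfinite(kappa):
            pi = rng.beta(mu * kappa, (1 - mu) * kappa, size=n)
        else:
            pi = np.full(n, mu)
        s_r = -t * (1 - pi)
        s_l = -t * pi
        n_left = config.left_handed.get(group, 0)
        n_fem = config.n_female.get(group, 0)
        hand = rng.permutation(["L"] * n_left + ["R"] * (n - n_left))
        sex = rng.permutation(["F"] * n_fem + ["M"] * (n - n_fem))
        for i in range(n):
            rows.append({"subject": f"{group}{sid + i + 1:03d}",
                         "group": group, "handedness": hand[i],
                         "sex": sex[i], "S_R_true": s_r[i],
                         "S_L_true": s_l[i],
                         "LI_true": s_r[i] - s_l[i]})
        sid += n
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


# -------------------------------------------------------------------- epochs
def _time_grid(config: SimulationConfig) -> np.ndarray:
    t0, t1 = config.epoch_window
    dt = 1000.0 / config.sampling_rate
    return t0 + dt * np.arange(int(round((t1 - t0) / dt)))


def _kernel(times: np.ndarray, latency: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - latency) / width) ** 2)


def measurement_gain(times: np.ndarray, sfreq: float, latency: float,
                     width: float, window: tuple[float, float],
                     baseline: tuple[float, float] = (-100.0, 0.0),
                     lowpass_hz: float = 30.0, order: int = 4) -> float:
    """Window-mean of a unit-peak kernel after the default measurement chain.

    The chain is baseline subtraction, forward-backward low-pass, then the
    inclusive-endpoint window mean on the sampling grid — the same sequence
    the preprocessing/measurement pipeline applies to averages.
    """
    k = _kernel(times, latency, width)
    bmask = (times >= baseline[0]) & (times < baseline[1])
    k = k - k[bmask].mean()
    k = lowpass_array(k[np.newaxis, :], sfreq, lowpass_hz, order)[0]
    wmask = (times >= window[0]) & (times <= window[1])
    if not wmask.any():
        raise ValueError("measurement window contains no samples")
    return float(k[wmask].mean())


def synthesize_epochs(truth: pd.DataFrame, config: SimulationConfig,
                      layout: ChannelLayout | None = None,
                      conditions: tuple[str, ...] = CONDITIONS) -> Epochs:
    """Generate trial-level epochs for the subjects in ``truth``.

    Deterministic given config.seed and the subject identities; each subject
    has an independent noise stream keyed by its position in the full truth
    table, so per-subject generation and whole-cohort generation agree.
    """
    layout = layout or ChannelLayout()
    times = _time_grid(config)
    channels = layout.channels
    n_ch, n_t = len(channels), len(times)
    ch_pos = {c: i for i, c in enumerate(channels)}

    gains = {name: measurement_gain(times, config.sampling_rate,
                                    spec.latency_ms, spec.width_ms,
                                    spec.window_ms)
             for name, spec in config.component_params.items()}

    blocks, infos = [], []
    for subj_idx, row in truth.reset_index(drop=True).iterrows():
        rng = _subject_rng(config.seed, 1, _stable_stream(row["subject"]))
        for cond in conditions:
            signal = np.zeros((n_ch, n_t))
            for name, spec in config.component_params.items():
                if cond not in spec.conditions:
                    continue
                k = _kernel(times, spec.latency_ms, spec.width_ms) / gains[name]
                base = spec.amplitude_for(row["group"])
                if spec.electrode_role == "hemisphere_sets":
                    # hemisphere x direction offsets: planted window-mean
                    # contralateral-minus-ipsilateral differences equal the
                    # true sensitivities exactly
                    sign = 1.0 if cond == "M_SL" else -1.0
                    for ch in layout.rh_set:
                        signal[ch_pos[ch]] += (
                            base + sign * row["S_R_true"] / 2.0) * k
                    for ch in layout.lh_set:
                        signal[ch_pos[ch]] += (
                            base - sign * row["S_L_true"] / 2.0) * k
                else:
                    for ch in getattr(layout, spec.electrode_role):
                        signal[ch_pos[ch]] += base * k
            trials = np.broadcast_to(
                signal, (config.n_trials, n_ch, n_t)).copy()
            if config.noise_sd > 0:
                trials += _noise(rng, (config.n_trials, n_ch, n_t),
                                 config, layout, channels)
            blocks.append(trials)
            info = pd.DataFrame({
                "subject": row["subject"], "group": row["group"],
                "handedness": row["handedness"], "condition": cond,
                "trial": np.arange(config.n_trials)})
            infos.append(info)
    data = np.concatenate(blocks, axis=0)
    info = pd.concat(infos, ignore_index=True)
    return Epochs(data, info, channels, times, config.sampling_rate)


def _stable_stream(subject: str) -> int:
    # deterministic per-subject stream id independent of dict/order effects
    digest = hashlib.blake2s(subject.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2 ** 31)


def _noise(rng: np.random.Generator, shape: tuple, config: SimulationConfig,
           layout: ChannelLayout, channels: list[str]) -> np.ndarray:
    """Mixed white / approximate-pink noise, unit-calibrated to noise_sd.

    Pink noise is approximated by standardized cumulative-summed white
    noise; spectral fidelity is not a goal.  EOG channels carry reduced
    background noise (ocular artifacts are injected separately).
    """
    white = rng.standard_normal(shape)
    f = config.pink_fraction
    if f > 0:
        walk = np.cumsum(rng.standard_normal(shape), axis=-1)
        walk -= walk.mean(axis=-1, keepdims=True)
        sd = walk.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        noise = np.sqrt(1 - f) * white + np.sqrt(f) * (walk / sd)
    else:
        noise = white
    noise *= config.noise_sd
    eog_idx = [i for i, c in enumerate(channels)
               if c in layout.eog_channels]
    noise[:, eog_idx, :] *= config.eog_noise_scale
    return noise


# ----------------------------------------------------------------- artifacts
def inject_artifacts(epochs: Epochs, config: SimulationConfig,
                     layout: ChannelLayout | None = None) -> Epochs:
    """Superimpose ocular/amplitude artifacts on a Bernoulli subset of trials.

    Adds boolean ``artifact_true`` and string ``artifact_kind`` columns to
    ``epochs.info`` as ground truth for rejection-accuracy tests.  Kinds:
    blink (large slow deflection on VEOG), hem (step on HEOG), spike
    (large excursion on one random analysis channel).
    """
    layout = layout or ChannelLayout()
    out = epochs.copy()
    n = out.n_epochs
    times = out.times
    t_mid = times[0] + (times[-1] - times[0]) / 2.0
    blink_shape = np.exp(-0.5 * ((times - t_mid) / 80.0) ** 2)
    step_shape = (times >= t_mid).astype(float)
    veog_idx = out.channel_index(layout.veog)
    heog_idx = out.channel_index([layout.heog])
    # spikes target non-reference scalp sites: a spike at a mastoid would be
    # shared into every channel (attenuated) by the offline re-reference
    spike_idx = out.channel_index(layout.occipital_set + layout.lh_set
                                  + layout.rh_set)
    amps = config.artifact_amplitudes
    flagged = np.zeros(n, dtype=bool)
    kinds = np.full(n, "none", dtype=object)
    # independent per-subject streams so subject-by-subject generation and
    # whole-cohort generation produce identical artifacts
    subjects = out.info["subject"].to_numpy()
    for subject in pd.unique(subjects):
        idx = np.nonzero(subjects == subject)[0]
        rng = _subject_rng(config.seed, 2, _stable_stream(subject))
        sub_flag = rng.random(len(idx)) < config.artifact_rate
        sub_kind = rng.choice(["blink", "hem", "spike"], size=len(idx))
        for j, i in enumerate(idx):
            if not sub_flag[j]:
                continue
            flagged[i] = True
            kinds[i] = sub_kind[j]
            if sub_kind[j] == "blink":
                out.data[i, veog_idx, :] += amps["blink"] * blink_shape
            elif sub_kind[j] == "hem":
                sign = 1.0 if rng.random() < 0.5 else -1.0
                out.data[i, heog_idx, :] += sign * amps["hem"] * step_shape
            else:
                ch = rng.choice(spike_idx)
                center = rng.integers(len(times) // 4, 3 * len(times) // 4)
                spike = np.exp(
                    -0.5 * ((np.arange(len(times)) - center) / 2.0) ** 2)
                out.data[i, ch, :] += amps["spike"] * spike
    out.info = out.info.assign(artifact_true=flagged,
                               artifact_kind=kinds.astype(str))
    return out


# ----------------------------------------------------------------- molecular
MOLECULAR_COLUMNS = ["subject", "measure_type", "feature", "batch", "value"]


def simulate_molecular(truth: pd.DataFrame,
                       config: SimulationConfig) -> pd.DataFrame:
    """Generate expression and methylation tables tied to the true LI.

    Expression features: latent z = rho * standardize(LI_true) +
    sqrt(1-rho^2) * noise, mapped onto two batch-specific affine scales
    (batches split by acquisition order = subject index parity).
    Methylation features: beta = inverse-logit(b0 + b1 * latent), latent
    built from the lead expression latent so promoter methylation opposes
    transcription; clipped to [0, 1] by construction of the inverse logit.
    """
    li = truth["LI_true"].to_numpy(dtype=float)
    n = len(li)
    if n < 2 or np.isclose(li.std(ddof=1), 0.0):
        raise ValueError("cannot standardize a degenerate LI distribution")
    li_z = (li - li.mean()) / li.std(ddof=1)
    rng = _subject_rng(config.seed, 3)
    batch_names = sorted(config.expression_batch_scales)
    batches = np.array([batch_names[i % len(batch_names)] for i in range(n)])

    rows = []
    lead_latent = None
    for feature, rho in config.expression_features.items():
        rho = config.rho_expression if rho is None else float(rho)
        eps = rng.standard_normal(n)
        latent = rho * li_z + np.sqrt(1 - rho ** 2) * eps
        if lead_latent is None:
            lead_latent = (latent, rho)
        for b in batch_names:
            mean, sd = config.expression_batch_scales[b]
            mask = batches == b
            for subj, val in zip(truth.loc[mask, "subject"],
                                 mean + sd * latent[mask]):
                rows.append((subj, "expression", feature, b, val))

    if config.methylation_features and lead_latent is None:
        raise ValueError("methylation features require at least one "
                         "expression feature to anchor to")
    e_lead, rho_lead = lead_latent if lead_latent is not None else (None, 0.0)
    for probe, rho_m in config.methylation_features.items():
        rho_m = config.rho_methylation if rho_m is None else float(rho_m)
        if abs(rho_m) > abs(rho_lead) or rho_lead == 0:
            raise ValueError(
                "methylation target correlation exceeds what the expression "
                f"latent can carry (|{rho_m}| > |{rho_lead}|)")
        b1 = rho_m / rho_lead
        m_latent = b1 * e_lead + np.sqrt(max(0.0, 1 - b1 ** 2)) \
            * rng.standard_normal(n)
        beta = expit(logit(0.3) + 0.5 * m_latent)
        for subj, val in zip(truth["subject"], beta):
            rows.append((subj, "methylation", probe, "meth", val))

    table = pd.DataFrame(rows, columns=MOLECULAR_COLUMNS)
    assert table.loc[table.measure_type == "methylation", "value"].between(
        0, 1).all()
    return table


class CohortSimulator:
    """Convenience wrapper bundling the generator stages.

    Examples
    --------
    >>> sim = CohortSimulator(SimulationConfig(seed=7))
    >>> truth = sim.truth()
    >>> mol = sim.molecular(truth)
    """

    def __init__(self, config: SimulationConfig | None = None,
                 layout: ChannelLayout | None = None) -> None:
        self.config = config or SimulationConfig()
        self.layout = layout or ChannelLayout()

    def truth(self) -> pd.DataFrame:
        return simulate_truth(self.config)

    def epochs(self, truth: pd.DataFrame, with_artifacts: bool = True,
               conditions: tuple[str, ...] = CONDITIONS) -> Epochs:
        ep = synthesize_epochs(truth, self.config, self.layout, conditions)
        if with_artifacts and self.config.artifact_rate > 0:
            ep = inject_artifacts(ep, self.config, self.layout)
        return ep

    def molecular(self, truth: pd.DataFrame) -> pd.DataFrame:
        return simulate_molecular(truth, self.config)
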