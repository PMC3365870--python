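"""Synthetic multichannel signals with graph-structured phase locking.

Generates EEG-like epochs (default 19 channels, 256 Hz, 20 s) from
coupled noisy phase oscillators,

    d theta_i = [ 2 pi f_c  +  kappa * sum_j A_ji sin(theta_j - theta_i) ] dt
                + sigma dW_i,
    x_i(t)    = sin(theta_i(t)) + measurement noise,

so that pairwise phase locking is controlled by the planted coupling
graph A (same directionality convention as the escape model: A_ji
couples node j's phase into node i).  A Kuramoto-type phase generator
is the right fixture for a phase-locking pipeline: the phase-locking
factor is a pure phase statistic, so amplitude realism would add
nothing that any pipeline stage can see.  It deliberately does not
emulate EEG spectra (no 1/f background, no artifacts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from escapenet.eeg_network import EEGRecord
from escapenet.graphs import DirectedGraph

__all__ = ["SyntheticEEGSpec", "generate", "generate_cohort"]


@dataclass(frozen=True)
class SyntheticEEGSpec:
    """Recipe for one synthetic multichannel epoch.

    ``carrier_hz`` is the common oscillator frequency (pick the centre
    of the analysis band); ``coupling_strength`` kappa (rad/s) pulls
    connected phases together against the phase diffusion
    ``phase_noise_sd`` (rad/sqrt(s)); ``measurement_noise_sd`` is white
    additive noise on the emitted signal (signal units; the carrier has
    amplitude 1).

    The default phase diffusion (12 rad/sqrt(s), coherence time ~15 ms)
    is deliberately stronger than a real alpha rhythm's: it makes the
    phase-coherence time short against a 20 s epoch, so uncoupled pairs
    sit at a clean near-zero PLF null (<~ 0.1) instead of the inflated
    small-sample plateau a slowly diffusing oscillator would show.
    Against that diffusion, kappa ~ 100-300 gives an intermediate PLF
    elevation and kappa >~ 1000 locks a mutually coupled pair almost
    completely (the stationary phase-difference concentration is
    2 kappa / phase_noise_sd^2).
    """

    n_channels: int = 19
    sample_rate: float = 256.0
    duration: float = 20.0
    carrier_hz: float = 10.0
    coupling_graph: DirectedGraph | None = None
    coupling_strength: float = 0.0
    phase_noise_sd: float = 12.0
    measurement_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration * self.sample_rate < 512:
            raise ValueError("need at least 512 samples (duration * sample_rate)")
        if self.coupling_strength < 0 or self.phase_noise_sd < 0:
            raise ValueError("coupling_strength and phase_noise_sd must be >= 0")
        if self.coupling_graph is not None and self.coupling_graph.n_nodes != self.n_channels:
            raise ValueError("coupling_graph size must equal n_channels")


def generate(spec: SyntheticEEGSpec) -> tuple[EEGRecord, DirectedGraph]:
    """One epoch of coupled-phase-oscillator signals plus its ground truth.

    Euler--Maruyama on the phases, internally oversampled so the
    coupling term stays well resolved (substep <= 0.2 / kappa) however
    strong the locking; phases are emitted at the output sampling rate.
    Initial phases uniform on [0, 2 pi).  Returns the record and the
    planted coupling graph (empty graph when none was given).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5EE9]))
    n = spec.n_channels
    graph = spec.coupling_graph or DirectedGraph.empty(n)
    a = graph.adjacency.astype(float)
    n_samples = int(round(spec.duration * spec.sample_rate))
    dt = 1.0 / spec.sample_rate
    kappa = spec.coupling_strength
    n_sub = max(1, math.ceil(kappa * dt / 0.2)) if kappa else 1
    dt_s = dt / n_sub
    sqdt_s = math.sqrt(dt_s)
    omega0 = 2 * math.pi * spec.carrier_hz

    theta = rng.uniform(0, 2 * math.pi, size=n)
    phases = np.empty((n, n_samples))
    for t in range(n_samples):
        phases[:, t] = theta
        for _ in range(n_sub):
            if kappa:
                # node i is pulled by senders j with A[j, i] = 1
                diff = np.sin(theta[:, None] - theta[None, :])  # diff[j, i] = sin(th_j - th_i)
                pull = kappa * np.einsum("ji,ji->i", a, diff)
            else:
                pull = 0.0
            theta = (
                theta
                + (omega0 + pull) * dt_s
                + spec.phase_noise_sd * sqdt_s * rng.standard_normal(n)
            )
    x = np.sin(phases)
    if spec.measurement_noise_sd:
        x = x + spec.measurement_noise_sd * rng.standard_normal(x.shape)
    labels = [f"CH{i:02d}" for i in range(n)]
    return EEGRecord(x, spec.sample_rate, labels), graph


def generate_cohort(
    n_subjects: int,
    group_spec: tuple[SyntheticEEGSpec, SyntheticEEGSpec],
    seed: int = 0,
    jitter: float = 0.1,
) -> list[tuple[EEGRecord, DirectedGraph, str]]:
    """Two-group cohort of records with per-subject parameter jitter.

    Subjects are split as evenly as possible between the two template
    specs (labels ``"A"`` and ``"B"``); each subject's coupling strength
    and phase noise are jittered by independent lognormal factors of
    scale ``jitter`` and the subject gets its own seed derived from
    ``seed``.  Returns ``[(record, planted graph, group label), ...]``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    master = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0C0]))
    out = []
    for k in range(n_subjects):
        group = k % 2  # interleave so uneven cohorts stay balanced
        template = group_spec[group]
        factor_k = math.exp(jitter * master.standard_normal())
        factor_s = math.exp(jitter * master.standard_normal())
        subject = replace(
            template,
            coupling_strength=template.coupling_strength * factor_k,
            phase_noise_sd=template.phase_noise_sd * factor_s,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        rec, g = generate(subject)
        out.append((rec, g, "A" if group == 0 else "B"))
    return out
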