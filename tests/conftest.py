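"""Shared fixtures: noise-free reference sessions and synthetic cohorts.

All fixtures are deterministic (fixed seeds) and generated in memory;
session-scoped cohorts are shared across test modules to keep the suite
fast.
"""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import settings

import duogait as dg
from duogait.config import RunConfig
from duogait.pipeline import extract_cohort_features
from duogait.simulate import ImpairmentEffect

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


def noise_free_spec(n_cycles: int = 12, seed: int = 1) -> dg.SimulationSpec:
    spec = dg.SimulationSpec(cycles_per_session=n_cycles, seed=seed)
    spec.noise = spec.noise.silent()
    spec.cycle_cv = 0.0
    spec.base_event_jitter_s = 0.0
    spec.asymmetry = 0.0
    return spec


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free 12-cycle reference session: timeline + both renders."""
    spec = noise_free_spec()
    tl = dg.sample_gait_timeline(spec, speed_class="normal")
    insole = dg.render_insole(tl, spec)
    imu_left, imu_right = dg.render_imu(tl, spec)
    return spec, tl, insole, imu_left, imu_right


@pytest.fixture(scope="session")
def default_cohort():
    """Full default cohort (19 subjects x 2 states x 3 speeds x 2 reps)
    with extracted feature tables from both pipelines."""
    spec = dg.SimulationSpec(seed=7)
    cohort = dg.generate_cohort(spec)
    ins, imu = extract_cohort_features(cohort, RunConfig(simulation=spec))
    return cohort, ins, imu


@pytest.fixture(scope="session")
def strong_cohort():
    """Normal-speed cohort with a strong impairment effect: any rated
    subject walks with >= 3x loading-response timing variability."""
    spec = dg.SimulationSpec(
        seed=7, speeds=("normal",),
        impairment=ImpairmentEffect(loading_response_std_per_rating=2.0))
    cohort = dg.generate_cohort(spec)
    ins, imu = extract_cohort_features(cohort, RunConfig(simulation=spec))
    return cohort, ins, imu


@pytest.fixture()
def worked_cycle():
    """The hand-checked cycle: t01=0, t02=0.12, t04=0.40, t05=0.50,
    t06=0.62, t07=0.65, t01'=1.00, t02'=1.12."""
    return dg.CycleTruth(t01=0.0, t02=0.12, t03=0.20, t04=0.40, t05=0.50,
                         t06=0.62, t07=0.65, t08=0.90, t01_next=1.00,
                         t02_next=1.12)


def spec_replace(spec: dg.SimulationSpec, **kwargs) -> dg.SimulationSpec:
    return dataclasses.replace(spec, **kwargs)
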