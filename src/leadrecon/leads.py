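"""Lead sets, limb-lead algebra, and 12-lead assembly.

The standard 12-lead ECG carries only 8 independent channels: leads I and II
plus the six precordial leads V1-V6.  The remaining four limb leads are exact
linear combinations (Einthoven / Goldberger relations)::

    III = II - I
    aVR = -(I + II) / 2
    aVL = I - II / 2
    aVF = II - I / 2

All amplitudes inside this package are in microvolts (uV); conversion from
other units happens at file boundaries (:func:`rescale_units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Canonical 12-lead order used for every 12-lead matrix in the package.
LEADS_12 = ("I", "II", "III", "aVR", "aVL", "aVF",
            "V1", "V2", "V3", "V4", "V5", "V6")

#: The 8 linearly independent leads, in canonical order.
INDEPENDENT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Limb leads derivable from I and II.
DERIVED_LEADS = ("III", "aVR", "aVL", "aVF")


class LeadError(ValueError):
    """Structured error for lead bookkeeping problems."""


@dataclass(frozen=True)
class MultiLeadSignal:
    """A bundle of equally sampled leads.

    Parameters
    ----------
    samples : ndarray, shape (n_leads, n_samples)
        Amplitudes in microvolts.
    sampling_rate : float
        Hz, > 0.
    lead_names : tuple of str
        Ordered, unique, one per row of ``samples``.
    """

    samples: np.ndarray
    sampling_rate: float
    lead_names: tuple

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise LeadError(f"samples must be 2-D (leads x time), got ndim={samples.ndim}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "lead_names", tuple(self.lead_names))
        if self.sampling_rate <= 0:
            raise LeadError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if len(self.lead_names) != samples.shape[0]:
            raise LeadError(
                f"{len(self.lead_names)} lead names for {samples.shape[0]} signal rows")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise LeadError(f"duplicate lead names in {self.lead_names}")

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Seconds."""
        return self.n_samples / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples (a view), by name."""
        try:
            idx = self.lead_names.index(name)
        except ValueError:
            raise LeadError(f"lead {name!r} not in {self.lead_names}") from None
        return self.samples[idx]

    def subset(self, names: Sequence[str]) -> "MultiLeadSignal":
        rows = np.stack([self.lead(n) for n in names])
        return MultiLeadSignal(rows, self.sampling_rate, tuple(names))


@dataclass(frozen=True)
class LeadSet:
    """Which leads are measured independently and which are derived."""

    independent: tuple = INDEPENDENT_LEADS
    derived: tuple = DERIVED_LEADS
    input_mode: tuple = ("I",)

    def __post_init__(self):
        if set(self.independent) & set(self.derived):
            raise LeadError("independent and derived lead sets overlap")
        if not set(self.input_mode) <= set(self.independent):
            raise LeadError(f"input leads {self.input_mode} not all independent")

    @property
    def n_input(self) -> int:
        return len(self.input_mode)

    @property
    def output_leads(self) -> tuple:
        """Independent leads the model must reconstruct (8 - n_input of them)."""
        return tuple(l for l in self.independent if l not in self.input_mode)


def one_lead_set() -> LeadSet:
    """Input lead I; reconstruct II, V1-V6."""
    return LeadSet(input_mode=("I",))


def two_lead_set() -> LeadSet:
    """Input leads I and II; reconstruct V1-V6."""
    return LeadSet(input_mode=("I", "II"))


def derive_limb_leads(lead_i: np.ndarray, lead_ii: np.ndarray):
    """Derive (III, aVR, aVL, aVF) from leads I and II, elementwise.

    Returns
    -------
    tuple of four ndarrays in that order.
    """
    lead_i = np.asarray(lead_i, dtype=float)
    lead_ii = np.asarray(lead_ii, dtype=float)
    if lead_i.shape != lead_ii.shape:
        raise LeadError(
            f"lead I has {lead_i.shape[-1]} samples but lead II has {lead_ii.shape[-1]}")
    iii = lead_ii - lead_i
    avr = -(lead_i + lead_ii) / 2.0
    avl = lead_i - lead_ii / 2.0
    avf = lead_ii - lead_i / 2.0
    return iii, avr, avl, avf


def assemble_12_lead(independent: MultiLeadSignal) -> MultiLeadSignal:
    """Build the canonical 12-lead signal from the 8 independent leads.

    The four limb leads III, aVR, aVL, aVF are derived from I and II; rows are
    returned in :data:`LEADS_12` order.
    """
    for name in INDEPENDENT_LEADS:
        if name not in independent.lead_names:
            raise LeadError(f"independent lead {name!r} missing from input")
    i, ii = independent.lead("I"), independent.lead("II")
    iii, avr, avl, avf = derive_limb_leads(i, ii)
    rows = [i, ii, iii, avr, avl, avf] + [independent.lead(v)
                                          for v in ("V1", "V2", "V3", "V4", "V5", "V6")]
    return MultiLeadSignal(np.stack(rows), independent.sampling_rate, LEADS_12)


def drop_derived(signal: MultiLeadSignal) -> MultiLeadSignal:
    """Keep only the 8 independent leads (inverse of :func:`assemble_12_lead`)."""
    return signal.subset(INDEPENDENT_LEADS)


def rescale_units(signal: MultiLeadSignal, factor: float) -> MultiLeadSignal:
    """Multiply all samples by ``factor`` (mV -> uV uses factor=1000)."""
    if factor <= 0:
        raise LeadError(f"rescale factor must be > 0, got {factor}")
    return replace(signal, samples=signal.samples * factor)
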