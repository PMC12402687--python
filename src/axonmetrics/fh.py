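"""Frankenhaeuser–Huxley (FH) membrane kinetics for nodes of Ranvier.

Voltage-gated sodium, potassium and non-specific permeabilities described by
Goldman–Hodgkin–Katz (constant-field) flux equations with gating variables
m, h, n, p, plus an ohmic leak.  Voltages throughout are *depolarizations*
from rest (``V = E_m - E_rest``, mV, rest −70 mV); rate constants are in
1/ms, currents in mA/cm².

Reference parameter set is at 20 °C; rates and permeabilities are scaled to
the simulation temperature with per-process Q10 factors.  The leak reversal
is recalibrated at model build time so that the resting state (V = 0 with
gates at steady state) is an exact equilibrium — without this, the published
constants leave a small residual current that would make a zero-drive axon
drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FHKinetics", "FH_REST_MV"]

#: resting membrane potential (mV, absolute)
FH_REST_MV = -70.0

_F = 96485.332  # C/mol
_R = 8.314462  # J/(mol K)
_T_REF_C = 20.0

# permeabilities cm/s, conductance mS/cm^2, concentrations mol/cm^3
_P_NA = 8.0e-3
_P_P = 0.54e-3
_P_K = 1.2e-3
_G_L = 30.3
_NA_O = 114.5e-6
_NA_I = 13.74e-6
_K_O = 2.5e-6
_K_I = 120.0e-6

# Q10 factors: (alpha, beta) per gate, one for permeabilities/leak
_Q10 = {
    "m": (1.8, 1.7),
    "h": (2.8, 2.9),
    "n": (3.2, 2.8),
    "p": (1.8, 1.7),
}
_Q10_PERM = 1.3


def _vtrap(num: np.ndarray, den: np.ndarray, limit: float) -> np.ndarray:
    """num/den with the analytic limit where den -> 0 (removable pole)."""
    small = np.abs(den) < 1e-9
    safe = np.where(small, 1.0, den)
    return np.where(small, limit, num / safe)


@dataclass(frozen=True)
class FHKinetics:
    """FH kinetics at a fixed temperature, with rest-exact leak.

    Parameters
    ----------
    temperature_c
        Simulation temperature in °C; Q10 scaling is applied relative to
        the 20 °C reference set.
    """

    temperature_c: float = 37.0

    @property
    def _t_kelvin(self) -> float:
        return 273.15 + self.temperature_c

    def _q(self, gate: str, which: int) -> float:
        return _Q10[gate][which] ** ((self.temperature_c - _T_REF_C) / 10.0)

    @property
    def _q_perm(self) -> float:
        return _Q10_PERM ** ((self.temperature_c - _T_REF_C) / 10.0)

    # -- gating rate constants (1/ms); V = depolarization in mV ------------

    def rates(self, v: np.ndarray) -> dict:
        """All eight rate constants at depolarization ``v`` (mV)."""
        v = np.asarray(v, dtype=float)
        am = 0.36 * _vtrap(v - 22.0, 1.0 - np.exp((22.0 - v) / 3.0), 3.0)
        bm = 0.4 * _vtrap(13.0 - v, 1.0 - np.exp((v - 13.0) / 20.0), 20.0)
        ah = 0.1 * _vtrap(-10.0 - v, 1.0 - np.exp((v + 10.0) / 6.0), 6.0)
        bh = 4.5 / (1.0 + np.exp((45.0 - v) / 10.0))
        an = 0.02 * _vtrap(v - 35.0, 1.0 - np.exp((35.0 - v) / 10.0), 10.0)
        bn = 0.05 * _vtrap(10.0 - v, 1.0 - np.exp((v - 10.0) / 10.0), 10.0)
        ap = 0.006 * _vtrap(v - 40.0, 1.0 - np.exp((40.0 - v) / 10.0), 10.0)
        bp = 0.09 * _vtrap(-25.0 - v, 1.0 - np.exp((v + 25.0) / 20.0), 20.0)
        return {
            "m": (am * self._q("m", 0), bm * self._q("m", 1)),
            "h": (ah * self._q("h", 0), bh * self._q("h", 1)),
            "n": (an * self._q("n", 0), bn * self._q("n", 1)),
            "p": (ap * self._q("p", 0), bp * self._q("p", 1)),
        }

    def steady_gates(self, v: np.ndarray) -> dict:
        """Steady-state gate values x_inf = a/(a+b) at depolarization v."""
        r = self.rates(v)
        return {g: a / (a + b) for g, (a, b) in r.items()}

    def resting_gates(self, shape) -> dict:
        """Gate arrays initialized to the resting steady state."""
        g0 = self.steady_gates(0.0)
        return {k: np.full(shape, float(v)) for k, v in g0.items()}

    # -- membrane currents --------------------------------------------------

    def _ghk(self, v: np.ndarray, p_cm_s: float, c_o: float, c_i: float
             ) -> np.ndarray:
        """GHK current density (mA/cm^2) for a monovalent cation."""
        em_volt = (np.asarray(v, dtype=float) + FH_REST_MV) * 1e-3
        xi = em_volt * _F / (_R * self._t_kelvin)
        exi = np.exp(xi)
        num = xi * (c_o - c_i * exi)
        den = 1.0 - exi
        frac = _vtrap(num, den, -(c_o - c_i))
        return p_cm_s * self._q_perm * _F * frac * 1e3  # A -> mA

    def ionic_current(
        self,
        v: np.ndarray,
        m: np.ndarray,
        h: np.ndarray,
        n: np.ndarray,
        p: np.ndarray,
        v_leak: float | np.ndarray,
    ) -> np.ndarray:
        """Total outward ionic current density (mA/cm^2)."""
        i_na = m * m * h * self._ghk(v, _P_NA, _NA_O, _NA_I)
        i_k = n * n * self._ghk(v, _P_K, _K_O, _K_I)
        i_p = p * p * self._ghk(v, _P_P, _NA_O, _NA_I)
        # leak: mS/cm^2 * mV = µA/cm^2, hence 1e-3 to express in mA/cm^2
        i_l = _G_L * self._q_perm * (v - v_leak) * 1e-3
        return i_na + i_k + i_p + i_l

    def rest_leak_reversal(self) -> float:
        """Leak reversal (depolarization, mV) that zeroes the net current at
        rest, making V = 0 an exact equilibrium."""
        g = self.steady_gates(0.0)
        i_active = self.ionic_current(
            np.asarray(0.0), g["m"], g["h"], g["n"], g["p"], v_leak=0.0
        )
        return float(i_active * 1e3 / (_G_L * self._q_perm))

    @property
    def g_leak(self) -> float:
        """Leak conductance at temperature (mS/cm^2)."""
        return _G_L * self._q_perm
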