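#!/usr/bin/env python
"""Poroelastic scaling of an intravitreal injection, plus numerical check.

Evaluates the closed-form advection time constant, Darcy velocity and
transport length for a 50 ul injection into a 1.2 cm vitreous, then runs
the radial Darcy oracle to confirm the time constant's order of magnitude.
Writes results/transport_scales.json.
"""

import json
from pathlib import Path

from vitreoflow import transport as tr

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = tr.PoroelasticParams(
        f=1.0, R0=1.2,
        a=tr.round_sig(tr.injection_radius(50.0), 2),
        kappa=8.4e-8,
        P0=tr.round_sig(tr.injection_overpressure(50.0, 1.0), 2),
    )
    scales = tr.transport_scales(params)
    prof = tr.simulate_relaxation(params)

    print(f"50 ul bolus radius a          = {params.a} cm")
    print(f"injection overpressure P0     = {params.P0:.3g} dyn/cm^2")
    print(f"advection time constant tau   = {scales.tau:.1f} s "
          f"(~{scales.tau / 60:.0f} min: the injection-driven flow persists "
          "for tens of minutes)")
    print(f"Darcy velocity scale V0       = {scales.V0:.3g} cm/s")
    print(f"transport length L0 = tau*V0  = {scales.L0:.2f} cm "
          "(larger than the globe: injected fluid can reach both retina "
          "and anterior segment)")
    print(f"numerical advection time      = {prof.fitted_time:.0f} s "
          f"(analytic/numerical = {scales.tau / prof.fitted_time:.2f}, "
          "order-of-magnitude agreement)")

    OUT.mkdir(exist_ok=True)
    report = tr.transport_report(params)
    report["numerical_advection_time_s"] = prof.fitted_time
    (OUT / "transport_scales.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
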