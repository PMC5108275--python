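#!/usr/bin/env python
"""Climate indices from monthly series, and recovery of imposed gradients.

Simulates monthly temperature/rainfall series whose site means follow
the published regional mean annual temperatures, computes the Kira
warmth/coldness indices, annual range, rainfall, and the hydrothermal
synthesis index per site, and checks that the imposed AMT ordering is
recovered by the index calculator.
"""

from pathlib import Path

from markerdiv.climate_indices import indices_for_sites
from markerdiv.synthetic_data import simulate_monthly_climate

SEED = 7
RESULTS = Path(__file__).resolve().parents[1] / "results"
AMT_TARGETS = [7.5, 6.9, 6.6, 5.9, 6.4]  # published regional means


def main() -> None:
    sites = simulate_monthly_climate(amt_targets=AMT_TARGETS, seed=SEED)
    table = indices_for_sites(sites)
    print("climate indices for the five simulated regional series:")
    print(table.round(2))
    order_in = [sorted(AMT_TARGETS).index(v) for v in AMT_TARGETS]
    order_out = table["AMT"].rank().astype(int).sub(1).tolist()
    print(f"AMT ordering recovered: {order_in == order_out}")
    print(
        "warm sites accumulate WI, cold sites CI; S rises with rainfall "
        "and falls with temperature"
    )
    RESULTS.mkdir(exist_ok=True)
    table.round(4).to_csv(RESULTS / "04_climate_indices.csv")
    print(f"wrote {RESULTS/'04_climate_indices.csv'}")


if __name__ == "__main__":
    main()
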