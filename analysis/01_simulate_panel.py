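"""Generate the synthetic monitoring panel the downstream analyses run on.

Emulates an annual large-river panel: 8 physico-chemical/microbiological
parameters at 10 stations over 17 years (2003-2019), with rising
nitrate+nitrite, falling conductivity and heavy-tailed coliform counts.
Writes results/panel.csv.
"""

from pathlib import Path

from riverwqi import brahmaputra_like, generate_panel, write_panel

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1729


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = brahmaputra_like(seed=SEED)
    panel = generate_panel(config)
    write_panel(panel, OUT / "panel.csv")
    wide = panel.wide()
    print(f"panel: {len(panel.stations)} stations x {len(panel.periods)} years"
          f" x {len(panel.parameters)} parameters ({len(panel.data)} values)")
    print("\nper-parameter summary:")
    print(wide.describe().loc[["mean", "std", "min", "max"]].T.round(2))
    print(f"\nwrote {OUT / 'panel.csv'}")


if __name__ == "__main__":
    main()
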