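"""Build the compartmented toy leaf network and verify its structure.

Writes the SBML model, light-curve parameters and scenario configs under
results/fixtures/, plus a balance report.  Prints the network size and the
energetic orderings the analysis rests on (ATP per photon of the
mitochondrial route vs the linear chloroplast chain).
"""

from pathlib import Path

import leafdiel as ld
from leafdiel.synthetic import mito_vs_linear_atp_per_photon

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    params = ld.ToyLeafParams()
    core = ld.build_toy_leaf(params)
    report = ld.validate_balance(core)
    outdir = RESULTS / "fixtures"
    files = ld.make_fixtures(outdir, params)
    report.to_tsv(RESULTS / "balance_report.tsv")

    diel = ld.build_diel(core, ld.toy_diel_config(params))
    print(f"core network: {len(core.reactions)} reactions, "
          f"{len(core.metabolites)} metabolites")
    print(f"diel model:   {len(diel.model.reactions)} reactions "
          f"({len(diel.linker_ids)} storage linkers)")
    print(f"balance: {len(report.checked)} reactions checked, "
          f"{'all balanced' if report.balanced else 'VIOLATIONS'}; "
          f"{len(report.exempt)} boundary/linker/photon reactions exempt")
    ratio = mito_vs_linear_atp_per_photon(params)
    print(f"ATP per photon, mitochondrial route / linear chain: {ratio:.3f} "
          f"(respiring NAD(P)H beats the linear chain ~2-fold)")
    print(f"wrote {len(files)} fixture files to {outdir}")


if __name__ == "__main__":
    main()
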