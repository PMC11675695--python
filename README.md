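# iftirt

Fisher-information diagnostics for improper solutions ("Heywood cases",
a.k.a. Guttman items) in item response theory.

Instead of scanning parameter estimates — which is hopeless for models with
hard-to-interpret parameters — the toolkit works from derivatives of the item
response function: item information curves, their critical points, and the
**Item Fraction of Total Information (IFTI)** decomposition
`IFTI_j(theta) = I_j(theta) / sum_k I_k(theta)`, a unitless per-theta share of
the test information. An item that hoards information (a spike in `I(theta)`,
or an IFTI above `2/J` / `4/J`) is flagged as suspect / troublesome /
problematic.

Supported families:

- **linear** latent-trait items (constant information `xi^2/psi^2`,
  `(1-h2)/h2` standardized; Bartlett scoring),
- **2PL / 3PL / 4PL** logistic items in slope-intercept form,
- **RH** (residual heteroscedasticity) items — a 2PL with a theta-dependent
  scale driven by an asymmetry parameter `delta`, reducing to the 2PL at
  `delta = 0`,
- **NRM** nominal (multinomial-logit) items under sum-to-zero identification.

Also included: EAP scoring with posterior SDs, score-volatility summaries by
number-correct, marginal maximum likelihood fitting of the 2PL/RH families
with optional Gaussian regularizing priors on `delta` (MAP), a prior-strength
sweep, and a fully seeded synthetic-data module.

## Library quick start

```python
import iftirt as ift

items = ift.rh_table1_itemset()            # 16-item RH exemplar set
grid = ift.ThetaGrid.regular()             # theta in [-4, 4], step 0.01
curves = ift.information_curves(items, grid)
report = ift.flag_items(items, curves, ift.ifti(curves))
print(report)                              # per-item flags + criteria

after = ift.drop_and_recompute(curves, ["MR3", "MR4"])  # renormalized IFTI
```

## Command line

```bash
iftirt info params.csv -o out/          # IRF/derivative/information curves
iftirt ifti params.csv --drop MR3       # IFTI, optionally after drops
iftirt detect params.csv --window -3 3  # Heywood report (CSV + log)
iftirt simulate params.csv -n 2000 --seed 7
iftirt fit responses.csv --family rh --prior-sd 0.5
iftirt sweep responses.csv --prior-sds inf,1,0.5
iftirt score params.csv responses.csv --method eap
```

Parameter tables are CSV/JSON (`item_id`, `family`, then `eta`, `xi`,
`psi2`/`h2`, `delta`, `c`, `d` or `alpha_k`/`gamma_k`); response matrices are
CSV with `NA` for missing. All curves are written as tidy long tables
(`item_id`, `theta`, `value`, `curve_type`). Every subcommand logs its seed
and a config hash, and is byte-reproducible given the same inputs.

## Layout

- `src/iftirt/irt_models.py` — item families, IRFs, exact derivatives,
  finite-difference fallback
- `src/iftirt/information.py` — item/category/test information, reliability,
  optimal weights
- `src/iftirt/heywood_diagnostics.py` — information peaks, IFTI,
  flagging thresholds, drop-and-recompute
- `src/iftirt/scoring.py` — Bartlett and EAP scores, volatility summary
- `src/iftirt/estimation.py` — MML / MAP fitting, prior sweep
- `src/iftirt/simdata.py` — seeded fixtures and response simulation
- `src/iftirt/cli_io.py` — file formats and the `iftirt` CLI
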