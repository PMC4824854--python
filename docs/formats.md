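# File formats

All exchange formats are plain text. Position labels in headers are
`P10` … `P1`, `P1p` … `P10p` (ASCII `p` = prime), ordered N→C.

## Cleavage-site table (TSV)

One row per site. Columns:

| column       | required | content                                                    |
| ------------ | -------- | ---------------------------------------------------------- |
| `peptide_id` | yes      | identifier of the peptide/protein the site lies in         |
| `sequence`   | yes      | full residue string, 1-letter codes, canonical 20 only     |
| `bond_after` | yes      | 1-based index i; cleavage between residues i and i+1       |
| `enzyme`     | no       | `C1`, `C2`, or `both`                                      |
| `status`     | no       | `Rp` (reported), `Nv` (novel), `Lit`, or `uncleaved`       |
| `kcat_km`    | no       | measured k_cat/K_m, M⁻¹s⁻¹                                 |
| `kcat_km_se` | no       | its standard error, M⁻¹s⁻¹                                 |

Malformed rows are rejected with their line number.

## Descriptor tables

* **AAindex1 flat file**: records keyed by the `H` accession line,
  values in the `I` block (two lines of ten, canonical
  A R N D C Q E G H I / L K M F P S T W Y V order). Records containing
  `NA` are skipped.
* **Generic TSV**: columns `descriptor_id`, optional `description`,
  and the 20 residue columns `A` … `Y`.
* **Secondary-structure probabilities** are per-window, not
  per-residue: supplied programmatically as a mapping
  `table_id -> {(window_id, position): probability}`.

## Intensity table (TSV)

Long format, one row per reporter channel:
`peptide_id`, `species` (`full_length` | `fragment`), `channel`
(113–121), `intensity` (non-negative, already standardized or raw).

## Model documents (JSON)

Versioned JSON with a `kind` field (`binary_qsar` | `pls_qsar`),
features as (position(s), descriptor) pairs, all fitted parameters,
and optionally the descriptor tables needed to score windows
self-containedly.

## Outputs

* Scan track TSV: `bond_after`, `p1`, `probability`, `called`,
  `scored` (bonds whose window lacks a model position are reported
  unscored rather than dropped).
* Logo TSV: `position`, `residue`, `count`, `proportion`, `r`
  (log₁₀ observed/background; −∞ floored at a display value).
* Kinetics TSV: `peptide_id`, `kcat_km`, `se`, `n_points`,
  `n_dropped`, `estimable`.
* Every CLI run writes `provenance.json` (options, package version,
  SHA-256 of inputs) and `run.log`.
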