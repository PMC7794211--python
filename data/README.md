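# Deposited field data

The eight pond-section treatment means of the original shading experiment
are archived in the Dryad repository (doi:10.5061/dryad.p8cz8w9ms) and are
not redistributed with this package.

To run the published-fit reproduction test
(`tests/test_acceptance.py::test_deposited_field_table_reproduces_published_fit`),
download the deposit and save the treatment means here as
`dryad_treatment_means.csv` with the standard treatment-table schema:

```
pond,treatment,h_ugC_L,p_ugC_L,cp_molar,edible_frac,mu,cpue
```

one row per pond × shading treatment (8 rows), biomasses in µg C L⁻¹,
seston C:P molar, μ in gC g chl-a⁻¹ d⁻¹ and CPUE in g wet weight.  Without
the file the test reports the missing input and fails.
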