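# Calibrated condition parameter sets: UP cost ratio (fraction of total
# protein), growth- and non-growth-associated maintenance, and the
# ribosomal-turnover schedule to use. Mirrors calibration.CONDITION_SETS.
chemostat_formate:    {up_ratio_c: 0.75, gam: 25.0,  ngam: 1.0, kcat_ribo_condition: formate}
chemostat_phosphate:  {up_ratio_c: 0.44, gam: 70.0,  ngam: 1.0, kcat_ribo_condition: phosphate}
batch_formate:        {up_ratio_c: 0.44, gam: 25.0,  ngam: 1.0, kcat_ribo_condition: formate}
chemostat_co2_h2:     {up_ratio_c: 0.44, gam: 130.0, ngam: 5.0, kcat_ribo_condition: formate}
batch_co2_h2:         {up_ratio_c: 0.20, gam: 25.0,  ngam: 5.0, kcat_ribo_condition: formate}
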