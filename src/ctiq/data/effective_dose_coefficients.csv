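# DLP-to-effective-dose coefficients W_T in mSv/(mGy.cm), keyed by body region,
# kVp band and age band.  Representative pediatric body values; editable
# configuration (coefficients below 80 kVp are not tabulated anywhere, so
# 70 kVp studies resolve to the 80 kVp row).
region,kvp,age_band,w_t_msv_per_mgycm
chest,80,pediatric,0.048
chest,100,pediatric,0.042
abdomen,80,pediatric,0.030
abdomen,100,pediatric,0.024
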