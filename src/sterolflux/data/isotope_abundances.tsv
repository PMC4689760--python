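# Stable-isotope masses (Da) and natural fractional abundances.
# Values follow the IUPAC/CIAAW 2013 representative compositions, rounded as
# commonly tabulated; abundances sum to 1 per element.
# columns: element	mass_da	abundance
H	1.0078250319	0.999885
H	2.0141017781	0.000115
C	12.0	0.9893
C	13.0033548351	0.0107
N	14.0030740044	0.99636
N	15.0001088989	0.00364
O	15.9949146196	0.99757
O	16.9991317565	0.00038
O	17.9991596129	0.00205
P	30.9737619984	1.0
S	31.9720711744	0.9499
S	32.9714589098	0.0075
S	33.9678670040	0.0425
S	35.9670807100	0.0001
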