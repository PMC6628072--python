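H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
R LIT:0807099b PMID:7108955
A Kyte, J. and Doolittle, R.F.
T A simple method for displaying the hydropathic character of a protein
J J. Mol. Biol. 157, 105-132 (1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
     3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7    -0.9    -1.3     4.2
//
H HOPT810101
D Hydrophilicity value (Hopp-Woods, 1981)
R LIT:0670633 PMID:6167991
A Hopp, T.P. and Woods, K.R.
T Prediction of protein antigenic determinants from amino acid sequences
J Proc. Natl. Acad. Sci. USA 78, 3824-3828 (1981)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    -0.5     3.0     0.2     3.0    -1.0     0.2     3.0     0.0    -0.5    -1.8
    -1.8     3.0    -1.3    -2.5     0.0     0.3    -0.4    -3.4    -2.3    -1.5
//
H GRAR740102
D Polarity (Grantham, 1974)
R LIT:2004143b PMID:4843792
A Grantham, R.
T Amino acid difference formula to help explain protein evolution
J Science 185, 862-864 (1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     8.1    10.5    11.6    13.0     5.5    10.5    12.3     9.0    10.4     5.2
     4.9    11.3     5.7     5.2     8.0     9.2     8.6     5.4     6.2     5.9
//
H ZIMJ680104
D Isoelectric point (Zimmerman et al., 1968)
R LIT:2004109b PMID:5700434
A Zimmerman, J.M., Eliezer, N. and Simha, R.
T The characterization of amino acid sequences in proteins by statistical methods
J J. Theor. Biol. 21, 170-201 (1968)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    6.00   10.76    5.41    2.77    5.05    5.65    3.22    5.97    7.59    6.02
    5.98    9.74    5.74    5.48    6.30    5.68    5.66    5.89    5.66    5.96
//
H FASG760101
D Molecular weight (Fasman, 1976)
R LIT:2004031b
A Fasman, G.D., ed.
T Handbook of Biochemistry and Molecular Biology, 3rd ed., Proteins - Volume 1
J CRC Press, Cleveland (1976)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   89.09  174.20  132.12  133.10  121.15  146.15  147.13   75.07  155.16  131.17
  131.17  146.19  149.21  165.19  115.13  105.09  119.12  204.23  181.19  117.15
//
H EISD840101
D Consensus normalized hydrophobicity scale (Eisenberg, 1984)
R LIT:2004199b PMID:6383201
A Eisenberg, D.
T Three-dimensional structure of membrane and surface proteins
J Ann. Rev. Biochem. 53, 595-623 (1984)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.62   -2.53   -0.78   -0.90    0.29   -0.85   -0.74    0.48   -0.40    1.38
    1.06   -1.50    0.64    1.19    0.12   -0.18   -0.05    0.81    0.26    1.08
//
H SYNTNA0001
D Synthetic incomplete entry (constructed in-house to exercise NA filtering)
R none
A none
T none
J none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.0      NA     1.0     1.0     1.0     1.0     1.0     1.0     1.0     1.0
     1.0     1.0     1.0      NA     1.0     1.0     1.0     1.0     1.0     1.0
//
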