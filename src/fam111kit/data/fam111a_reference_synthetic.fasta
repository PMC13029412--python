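>NP_001361777.1-synthetic-surrogate synthetic stand-in for human FAM111A isoform 1 (constructed from published residue annotations, not the database record) [Homo sapiens]
KAGGVGKGTHTTNKEQKEIQVFYVLDNICYQSRGHLARFTTNIANIYEALFPNYDPYICS
IHGMGKSMRSCWNMEPWDDLVQEDVHCGLDDWTDNCRVWTIGNTESRINKTHRMSTGMLW
WTDTSRFWLRYYWHTWPYNVWYKIFCAINEWAQYAPPDTETWEMQEWWKTLESGPFNYCL
NNIEAMCIFDGCGKSHFMCAVIFFVPICWWMMEQIIVQGEKHCALCVDGRFCFFSSRTWH
IESWGNCRRDGSKKWQVPLPELDWEKERHRGQMRFHDTLGWPLYEVRGVCALLHYDKCDV
FARAISHMIWIYCPWRPEITWYGIHLCSMGWHAFGAFTHDNSGPTEEIECITYHISVKHI
IWCCNGPPYNQEKNVYLRDIITTRHVVQDMKDTQNYSLDTQNMLCLTFNYSMSRVQMSWL
WKLQQCVLAKCWHTPQLYDVADLWLMMKFRHNMFPYKWTREICLHNIIGHPIGMYKNPME
GQRACANPHPAFFTNCWMLKMIVKLGINRCYGYMWCVGSFKNKQGDPDNRQMWDEFFFGE
SGSPVTDDQCTLPKMHAAGFIYDFYHFSRTMIEFLIQLIWNHCAWKQTMECRRFWRGMMR
DPYAWSVPAFL
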