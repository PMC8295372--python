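>III.d1.r1 synthetic reference domain
WRKYGQKIYQKESKPCPIKVSCTEKDYQFSSIQDMNARVRNYKHLC
>III.d1.r2 synthetic reference domain
WRKYGQKKLQMIPMDCKIAAGCGTVSMQQLLYLTKGTNNYDSFHKC
>III.d1.r3 synthetic reference domain
WRKYGQKTLFMRVDRCSKFLECDGMPFGDMDIFAQAFKNYPIYHRC
>III.d1.r4 synthetic reference domain
WRKYGQKLKSAAAPLCYPAVVCGEEQDAIDFEVVESDQVQFGVHMC
>IIa.d1.r1 synthetic reference domain
WRKYGQKDMMYTLGRCVKEVFCPVKKKLQTYYSFITIMQMTNPHDH
>IIa.d1.r2 synthetic reference domain
WRKYGQKPTLPGDKRCIDGKLCPVKKKLQQDLRDVPMKLKQERHFH
>IIa.d1.r3 synthetic reference domain
WRKYGQKYYFPTNPSCAKAENCPVKKKLQPTKSKADTLFAFVEHKH
>IIa.d1.r4 synthetic reference domain
WRKYGQKIRKPDLNICQADQPCPVKKKLQDNFMYFKSKSQNGSHKH
>IIb.d1.r1 synthetic reference domain
WRKYGQKVIDQKDSKCVYTPGCPVRKQVQMTGQARVDVDYMMDHPH
>IIb.d1.r2 synthetic reference domain
WRKYGQKFGDTDNNICDIGKMCPVRKQVQQVSTDSVRRESNFTHEH
>IIb.d1.r3 synthetic reference domain
WRKYGQKGRFVDISDCKIQTECPVRKQVQTQFMEGMQIRTELAHFH
>IIb.d1.r4 synthetic reference domain
WRKYGQKKLIFDQRYCIPDGLCPVRKQVQSYKTDGENKFTTFGHSH
>IIc.d1.r1 synthetic reference domain
WRKYGQKPDMTVRFDCVAFGCMFVQIMENTGMYLDIQANLYSHYHD
>IIc.d1.r2 synthetic reference domain
WRKYGQKMQLKKAEYCQDVSCMGVRGFGFYKVFMTNEKYAGKHFHY
>IIc.d1.r3 synthetic reference domain
WRKYGQKQMFSEELRCSPMYCFITLSGMRRDYRITGGGKAISHTHR
>IIc.d1.r4 synthetic reference domain
WRKYGQKELVTDEAYCSRDACNEMDVQQSYSQFIKVQDQQVDHDHF
>IId.d1.r1 synthetic reference domain
WRKYGQKQKNMSAVKCRNYGSCPARKHVEKYSNFEIVGYGEAKHYH
>IId.d1.r2 synthetic reference domain
WRKYGQKQMDIDTFACIDSARCPARKHVEAVARPFRGKKVYRDHYH
>IId.d1.r3 synthetic reference domain
WRKYGQKISTMTAKECQISENCPARKHVEPSDENAKAKRDIRQHRH
>IId.d1.r4 synthetic reference domain
WRKYGQKYIEKVQAECIPIIPCPARKHVEQTPMITGFKNIKRPHSH
>IIe.d1.r1 synthetic reference domain
WRKYGQKFMRGAMKRCMNMAGCPARKQVEDGKDTKLLPMNTDYHMH
>IIe.d1.r2 synthetic reference domain
WRKYGQKELGLNVEICKYAMGCPARKQVEMTRSMIDSNGDMVNHIH
>IIe.d1.r3 synthetic reference domain
WRKYGQKEVGMISDMCGFGYNCPARKQVEPSLPVFNMKEFPIQHSH
>IIe.d1.r4 synthetic reference domain
WRKYGQKGEVLNPQLCMKFATCPARKQVESADVLYDKIKSLVTHAH
>Ia.d1.r1 synthetic reference domain
WRKYGQKYIFQLKPYCDEMECSRPQTVIDAAQEGVRLQLRGQHFHI
>Ia.d1.r2 synthetic reference domain
WRKYGQKDKRRARRTCMAFVCFAARTIPVRRNQDDRIVTGIKHAHY
>Ia.d1.r3 synthetic reference domain
WRKYGQKIPSEIEEGCLVVSCDAYNSFGGVMIFKQPAPAEGYHDHF
>Ia.d1.r4 synthetic reference domain
WRKYGQKTESTNERPCALGQCMESMPSIVGQTNNSTKDLSPDHYHI
>Ia.d2.r1 synthetic reference domain
WRKYGQKSKFDRVKLCRDGQCFIRPAQGYMNVPPYEIIIIREHPHV
>Ia.d2.r2 synthetic reference domain
WRKYGQKIYVVYLYNCQTTDCVMPMVTNLIKMKERYPEEIGEHIHT
>Ia.d2.r3 synthetic reference domain
WRKYGQKSRGTEVTSCDPIQCITIERFKNKMQVKIKDRGQFAHLHQ
>Ia.d2.r4 synthetic reference domain
WRKYGQKDDPQKQFPCVYYGCQFDKMEQYLRESIRVSAYAIQHIHT
>Ib.d1.r1 synthetic reference domain
WRKYGQKAPKVAMAQCLLPSGCAVKPKVDYMIRPESYGFSVTAHYC
>Ib.d1.r2 synthetic reference domain
WRKYGQKMVDPIESICPTVAMCGDKDGMQVFYFRTDQEVPTPLHVC
>Ib.d1.r3 synthetic reference domain
WRKYGQKMMDGDEDRCFVKRACESPLVTMFATGIQLEPIRYQEHRC
>Ib.d1.r4 synthetic reference domain
WRKYGQKLPQRFISYCEGPPACAYKMKGIEDAEGVTQGMVSYKHNC
>Ib.d2.r1 synthetic reference domain
WRKYGQKVDIILQEKCKQPQICERITQNMFMNESVNADRKGPSHAC
>Ib.d2.r2 synthetic reference domain
WRKYGQKILSRPNYKCRVVVICIQAQFFRSSNIVVMLTMIEIEHNC
>Ib.d2.r3 synthetic reference domain
WRKYGQKPDLLKVFQCAVTVNCDTGERILVSQMPFNGENVVVAHFC
>Ib.d2.r4 synthetic reference domain
WRKYGQKMANDVEAGCKIRFFCVQRGMNQNLDDNNMKFTAMSVHLC
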