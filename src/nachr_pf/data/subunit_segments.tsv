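species	name	accession	seg_m5m4	seg_m3_0	seg_1_18	seg_19	seg_20	seg_21_24	seg_25_29
H	α1	P02708	DS	_GEK	MTLSISVLLSLTVFLLVI	V	E	LIPS	TSSAV
H	β1	P11230	DA	_GEK	MGLSIFALLTLTVFLLLL	A	D	KVPE	TSLSV
H	γ	P07510	KA	GGQK	CTVAINVLLAQTVFLFLV	A	K	KVPE	TSQAV
H	δ	Q07001	DS	_GEK	TSVAISVLLAQSVFLLLI	S	K	RLPA	TSMAI
H	ε	Q04844	QA	GGQK	CTVSINVLLAQTVFLFLI	A	Q	KIPE	TSLSV
M	α1	P04756	DS	_GEK	MTLSISVLLSLTVFLLVI	V	E	LIPS	TSSAV
M	β1	P09690	DA	_GEK	MGLSIFALLTLTVFLLLL	A	D	KVPE	TSLAV
M	γ	P04760	KA	GGQK	CTVATNVLLAQTVFLFLV	A	K	KVPE	TSQAV
M	δ	P02716	DC	_GEK	TSVAISVLLAQSVFLLLI	S	K	RLPA	TSMAI
M	ε	P20782	QA	GGQK	CTVSINVLLAQTVFLFLI	A	Q	KIPE	TSLSV
H	α2	Q15822	DC	_GEK	ITLCISVLLSLTVFLLLI	T	E	IIPS	TSLVI
H	α3	P32297	DC	_GEK	VTLCISVLLSLTVFLLVI	T	E	TIPS	TSLVI
H	α4	P43681	EC	_GEK	ITLCISVLLSLTVFLLLI	T	E	IIPS	TSLVI
H	α5	P30532	NE	_GEK	ICLCTSVLVSLTVFLLVI	E	E	IIPS	SSKVI
H	α6	Q15825	DC	_GEK	VTLCISVLLSLTVFLLVI	T	E	TIPS	TSLVV
H	α7	P36544	DS	_GEK	ISLGITVLLSLTVFMLLV	A	E	IMPA	TSDSV
H	β2	P17787	DC	_GEK	MTLCISVLLALTVFLLLI	S	K	IVPP	TSLDV
H	β4	P30926	DC	_GEK	MTLCISVLLALTFFLLLI	S	K	IVPP	TSLDV
M	α4	O70174	EC	_GEK	VTLCISVLLSLTVFLLLI	T	E	IIPS	TSLVI
M	α5	Q2MKA5	NE	_GEK	ISLCTSVLVSLTVFLLVI	E	E	IIPS	SSKVI
M	β2	Q9ERK7	DC	_GEK	MTLCISVLLALTVFLLLI	S	K	IVPP	TSLDV
R	α7	Q05941	DS	_GEK	ISLGITVLLSLTVFMLLV	A	E	IMPA	TSDSV
R	α9	P43144	AS	_GEK	VSLGVTILLAMTVFQLMV	A	E	IMPA	SENVP
R	α10	Q9JLB5	DS	_GEK	VSLGVTVLLALTVFQLIL	A	E	SMPP	AESVP
C	α3	P09481	DC	_GEK	VTLCISVLLSLTVFLLVI	T	E	TIPS	TSLVI
C	α4	P09482	EC	_GEK	ITLCISVLLSLTVFLLLI	T	E	IIPS	TSLVI
C	β2	P09484	DC	_GEK	MTLCISVLLALTVFLLLI	S	K	IVPP	TSLDV
C	β4	P26153	DC	_GEK	MTLCISVLLALTVFLLLI	S	K	IVPP	TSLDV
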