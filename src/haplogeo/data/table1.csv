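code,locality,flower_color,habit,n,latitude,longitude,region,H1,H2,H3,H4,H5,H6,H7,H8,H9,H10,H11,H12,H13,H14,H15,H16
BT,"Batang, Sichuan",R,P,15,30°03'54.2″,099°08'56.8″,SEQTP,0,0,0,0,0,0,0,0,0,0,0,0,0,15,0,0
CH,"Chifeng, Neimenggu",R,A,15,42°45'38.2″,119°43'17.5″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
CP,"Changping, Beijing",R,A,15,40°18'17.1″,116°22'51.6″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
DB,"Bashong, Derong, Sichuan",R,P,15,29°19'41.6″,099°11'56.4″,SEQTP,0,0,0,0,0,0,0,0,0,0,0,0,0,15,0,0
DQ,"Yanjing, Tibet",R,A,15,28°36'11.7″,098°45'32.7″,SEQTP,0,0,0,0,0,0,0,0,0,0,0,0,0,0,15,0
DR,"Derong, Sichuan",R,P,15,28°47'39.1″,099°17'36.4″,SEQTP,0,0,0,0,0,0,0,0,0,0,0,0,0,0,15,0
DS,"Danba, Sichuan",R,P,15,30°51'28.0″,101°51'15.2″,SEQTP,0,0,0,0,0,0,0,0,0,0,0,9,0,0,0,6
GA,"Dingxi, Gansu",Y,P,15,35°38'11.0″,104°34'42.7″,NEQTP,0,0,0,0,0,0,9,6,0,0,0,0,0,0,0,0
GD,"Diebu, Gansu",Y,P,15,33°56'44.0″,103°39'17.4″,NEQTP,0,0,0,0,0,0,0,0,0,15,0,0,0,0,0,0
GG,"Lanzhou, Gansu",Y,P,15,35°56'54.1″,103°52'22.4″,NEQTP,0,0,0,0,0,0,15,0,0,0,0,0,0,0,0,0
GL,"Tianshui, Gansu",Y,P,15,34°32'56.7″,105°43'19.4″,NEQTP,0,0,0,0,0,0,15,0,0,0,0,0,0,0,0,0
GW,"Wenxian, Gansu",R,P,15,32°57'52.6″,104°39'07.2″,NEQTP,0,0,0,0,0,0,0,0,15,0,0,0,0,0,0,0
GY,"Yongdeng, Gansu",Y,P,15,36°32'48.2″,102°56'13.4″,NEQTP,0,0,0,0,0,0,15,0,0,0,0,0,0,0,0,0
HL,"Huanling, Shensi",R,A,15,35°33'19.1″,109°15'52.3″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
HQ,"Hequ, Shansi",R,A,15,39°23'06.8″,111°08'20.1″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
HS,"Hengshan, Shensi",R,A,15,37°58'39.1″,109°45'05.1″,N,8,0,0,0,0,7,0,0,0,0,0,0,0,0,0,0
HR,"Heshui, Gansu",R,A,15,35°38'39.5″,107°53'19.4″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
JB,"Jingbian, Shensi",R,A,15,37°35'44.6″,108°46'29.3″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
JC,"Jinchuan, Gansu",R,A,15,35°20'59.7″,107°26'24.7″,N,9,0,3,0,0,3,0,0,0,0,0,0,0,0,0,0
JM,"Jinchuan, Sichuan",R,P,15,31°14'04.1″,102°00'31.6″,SEQTP,0,0,0,0,0,0,0,0,0,0,0,15,0,0,0,0
JX,"Jiaxian, Shensi",R,A,15,38°02'00.6″,110°28'57.4″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
LS,"Jincheng, Shansi",R,A,15,35°27'34.5″,113°03'55.3″,N,8,0,0,0,0,7,0,0,0,0,0,0,0,0,0,0
LT,"Liancheng, Gansu",R,P,15,36°41'15.8″,102°44'44.4″,NEQTP,0,0,0,0,0,0,15,0,0,0,0,0,0,0,0,0
LX,"Linxian, Shansi",R,A,15,38°07'56.8″,111°03'13.1″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
LY,"Laiyuan, Hebei",R,A,15,39°22'04.6″,114°42'31.0″,N,0,0,0,0,0,15,0,0,0,0,0,0,0,0,0,0
MD,"Molidawaqi, Neimenggu",R,A,15,48°20'49.6″,124°26'51.4″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
MG,"Maixian, Sichuan",R,P,15,31°48'26.8″,103°50'29.0″,SEQTP,0,0,0,0,0,0,0,0,0,0,15,0,0,0,0,0
MS,"Maerkang, Sichuan",R,P,15,31°54'57.6″,102°06'01.9″,SEQTP,0,0,0,0,0,0,0,0,0,0,0,0,15,0,0,0
MZ,"Mizhi, Shensi",R,A,15,37°42'46.7″,110°10'45.4″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
NZ,"Zhuozi, Neimenggu",R,A,15,40°53'46.0″,112°35'02.8″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
PS,"Pingshan, Hebei",R,A,15,38°18'46.9″,113°59'41.4″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
QQ,"Qiqihaer, Heilongjiang",R,A,15,47°20'23.0″,123°57'44.7″,N,2,8,0,0,5,0,0,0,0,0,0,0,0,0,0,0
SD,"Dabaodang, Shenmu, Shensi",R,A,15,38°40'30.8″,110°02'56.5″,N,13,0,0,2,0,0,0,0,0,0,0,0,0,0,0,0
SS,"Shenmu, Shensi",R,A,15,38°55'02.0″,110°28'26.8″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
SZ,"Suizhong, Liaoning",R,A,15,40°10'59.5″,119°48'49.7″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
WG,"Wutai, Shansi",R,A,15,38°40'04.7″,113°12'55.6″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
XM,"Xianyang, Shensi",R,A,15,34°20'09.6″,108°34'11.8″,N,11,0,0,0,4,0,0,0,0,0,0,0,0,0,0,0
XN,"Xining, Qinghai",Y,P,15,36°37'48.4″,101°43'55.6″,NEQTP,0,0,0,0,0,0,15,0,0,0,0,0,0,0,0,0
XT,"Xintai, Shandong",R,A,15,35°44'53.4″,117°28'45.6″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
XX,"Xingxian, Shansi",R,A,15,38°28'14.5″,111°14'07.5″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
XY,"Xiuyan, Liaoning",R,A,15,40°49'28.2″,123°07'18.5″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
XZ,"Xinzhou, Shansi",R,A,15,38°17'19.6″,112°42'31.8″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
YA,"Yanan, Shensi",R,A,15,36°29'47.4″,109°28'42.0″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
YC,"Yijinhuoluoqi, Neimenggu",R,A,15,39°21'45.4″,109°49'40.1″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
YH,"Yinchuan, Ninxia",R,A,15,38°42'27.1″,105°57'29.9″,N,15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
YJ,"Yongji, Shansi",R,A,15,34°50'40.7″,110°20'24.5″,N,5,0,0,0,0,10,0,0,0,0,0,0,0,0,0,0
ZZ,"Zezhou, Shansi",R,A,15,35°30'29.7″,113°03'03.3″,N,6,0,0,0,0,9,0,0,0,0,0,0,0,0,0,0
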